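"""End-to-end orchestration: simulate/ingest -> IC -> annotate -> diff -> screens.

Each organism is processed the way the study design dictates: its sample
columns are quantile-normalised per extract phase, features are
annotated against the organism-restricted compound library, the two
phases are merged by logP, and fold-changes with Storey-corrected
t-tests are computed against the unstressed control. Organism-level
results are then pooled into the cross-species comparisons and screens.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotation as ann
from . import comparative, differential, screens
from .dose_response import OrganismICEstimate, estimate_ic_from_curves
from .io import CompoundLibrary, IonTable, OrganismMeta
from .simulate import StudyBundle


def _subset_for_organism(table: IonTable, organism_id: str) -> IonTable:
    design = table.design[table.design["organism_id"] == organism_id]
    cols = [c for c in table.samples if c in design.index]
    return IonTable(
        mz=table.mz,
        intensities=table.intensities[cols],
        design=design.reset_index(drop=True),
    )


def differential_for_organism(
    polar: IonTable,
    nonpolar: IonTable,
    lib: CompoundLibrary,
    organism_id: str,
    tolerance: float = ann.DEFAULT_TOLERANCE,
    fc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, ann.MetaboliteTable]:
    """Normalise, annotate, merge and differential-call one organism."""
    tabs = {}
    for phase, table in (("polar", polar), ("nonpolar", nonpolar)):
        sub = _subset_for_organism(table, organism_id)
        norm = differential.quantile_normalize(sub.intensities)
        tabs[phase] = IonTable(mz=sub.mz, intensities=norm, design=sub.design)
    annotations = {
        phase: ann.annotate_ions(tabs[phase], lib, organism_id, tolerance)
        for phase in tabs
    }
    metab = ann.merge_extracts(tabs["polar"], tabs["nonpolar"], annotations, lib)
    records = differential.log2_fold_changes(metab)
    records = differential.call_differential(records, fc_threshold, alpha)
    return records, metab


@dataclass
class StudyResults:
    """Everything the pipeline computed for one (synthetic) study."""

    ic_estimates: dict[str, OrganismICEstimate]
    records: pd.DataFrame  # pooled fold-change records, all organisms
    row_metabolite: dict[str, str]  # annotated row id -> metabolite id
    fc_ic50: pd.DataFrame  # row id x organism log2FC at IC50
    screen: list[screens.ScreenResult] = field(default_factory=list)
    anova: list[screens.AnovaResult] = field(default_factory=list)
    anova_hits: dict[str, pd.DataFrame] = field(default_factory=dict)
    anova_union: int = 0
    mantel: comparative.MantelResult | None = None

    def summary(self) -> str:
        n_org = self.records["organism_id"].nunique()
        n_diff = (
            self.records[self.records["differential"]]
            .groupby("organism_id")["metabolite_id"]
            .nunique()
        )
        hits = [s for s in self.screen if s.is_hit]
        lines = [
            "Cross-species salt-stress study results",
            "=======================================",
            f"{'organisms':<34}{n_org:>8}",
            f"{'annotated ion rows':<34}{len(self.row_metabolite):>8}",
            f"{'differential metabolites (mean)':<34}{n_diff.mean() if len(n_diff) else 0:>8.1f}",
            f"{'ANOVA hit union':<34}{self.anova_union:>8}",
            f"{'tolerance-screen hits':<34}{len(hits):>8}",
        ]
        if self.mantel is not None:
            lines.append(f"{'Mantel R (IC50)':<34}{self.mantel.r:>8.3f}")
            lines.append(f"{'Mantel permutation p':<34}{self.mantel.p_perm:>8.4g}")
        return "\n".join(lines)


def fold_change_matrix(
    records: pd.DataFrame, level: str = "IC50", value: str = "log2fc"
) -> pd.DataFrame:
    """Pivot pooled records to a (row id x organism) matrix at one level."""
    sub = records[records["stress_level"] == level]
    return sub.pivot_table(
        index="metabolite_id", columns="organism_id", values=value, aggfunc="first"
    )


def run_study(
    bundle: StudyBundle,
    tolerance: float = ann.DEFAULT_TOLERANCE,
    n_perm: int = 999,
    seed: int | None = None,
    with_anova: bool = True,
    with_mantel: bool = True,
    use_estimated_ic50: bool = True,
) -> StudyResults:
    """Run the complete analysis pipeline on a study bundle."""
    ic_estimates: dict[str, OrganismICEstimate] = {}
    if bundle.growth is not None:
        for org, curves in bundle.growth.items():
            ic_estimates[org] = estimate_ic_from_curves(curves)

    all_records = []
    row_metabolite: dict[str, str] = {}
    for meta in bundle.metas:
        records, metab = differential_for_organism(
            bundle.polar, bundle.nonpolar, bundle.library, meta.organism_id, tolerance
        )
        records["organism_id"] = meta.organism_id
        all_records.append(records)
        row_metabolite.update(metab.meta["metabolite_id"].to_dict())
    records = pd.concat(all_records, ignore_index=True)

    fc_ic50 = fold_change_matrix(records, "IC50")

    if use_estimated_ic50 and ic_estimates:
        ic50s = {o: est.ic50 for o, est in ic_estimates.items()}
    else:
        ic50s = {m.organism_id: m.ic50 for m in bundle.metas}
    screen_results = screens.tolerance_screen(fc_ic50, ic50s)

    anova_results: list[screens.AnovaResult] = []
    anova_hits: dict[str, pd.DataFrame] = {}
    union = 0
    if with_anova:
        metas_est = []
        for m in bundle.metas:
            mm = OrganismMeta(
                organism_id=m.organism_id,
                display_name=m.display_name,
                taxonomy_group=m.taxonomy_group,
                habitat=m.habitat,
                cell_wall=m.cell_wall,
                ic50=ic50s.get(m.organism_id, m.ic50),
                n_bio_replicates=m.n_bio_replicates,
            )
            metas_est.append(mm)
        anova_results = screens.fourway_anova(fc_ic50, metas_est)
        anova_hits, union = screens.select_anova_hits(anova_results)

    mantel = None
    if with_mantel and bundle.alignment is not None:
        d_met = comparative.cityblock_distances(fc_ic50.T)
        d_phy = comparative.jukes_cantor_distances(bundle.alignment)
        order = [lb for lb in d_met.labels if lb in d_phy.labels]
        idx1 = [d_met.labels.index(lb) for lb in order]
        idx2 = [d_phy.labels.index(lb) for lb in order]
        d1 = comparative.DistanceMatrix(
            order, d_met.values[np.ix_(idx1, idx1)], metric=d_met.metric
        )
        d2 = comparative.DistanceMatrix(
            order, d_phy.values[np.ix_(idx2, idx2)], metric=d_phy.metric
        )
        mantel = comparative.distance_correlation_test(d1, d2, n_perm=n_perm, seed=seed)

    return StudyResults(
        ic_estimates=ic_estimates,
        records=records,
        row_metabolite=row_metabolite,
        fc_ic50=fc_ic50,
        screen=screen_results,
        anova=anova_results,
        anova_hits=anova_hits,
        anova_union=union,
        mantel=mantel,
    )


def screen_confusion(
    results: StudyResults, truth, row_metabolite: dict[str, str] | None = None
) -> dict[str, float]:
    """Sensitivity and false-positive rate of the tolerance screen against
    the generator's planted-effect registry (metabolite level: a planted
    metabolite counts as recovered when any of its annotated ion rows is a
    hit in the planted direction)."""
    row_met = row_metabolite or results.row_metabolite
    planted_pos = truth.metabolites_of_class("tolerance-correlated-positive")
    planted_neg = truth.metabolites_of_class("tolerance-correlated-negative")
    nulls = truth.metabolites_of_class("null")
    hit_dir: dict[str, set[str]] = {}
    for s in results.screen:
        met = row_met.get(s.metabolite_id, s.metabolite_id)
        hit_dir.setdefault(met, set())
        if s.is_hit:
            hit_dir[met].add(s.hit_direction)
    tp = sum(1 for m in planted_pos if "correlating" in hit_dir.get(m, set()))
    tp += sum(1 for m in planted_neg if "anticorrelating" in hit_dir.get(m, set()))
    n_planted = len(planted_pos) + len(planted_neg)
    considered_nulls = [m for m in nulls if m in hit_dir]
    fp = sum(1 for m in considered_nulls if hit_dir[m])
    return {
        "sensitivity": tp / n_planted if n_planted else float("nan"),
        "fpr": fp / len(considered_nulls) if considered_nulls else 0.0,
        "n_planted": n_planted,
        "n_null": len(considered_nulls),
    }
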