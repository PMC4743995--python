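"""Hit-finding screens over the high-stress (IC50) fold-change matrix.

Two procedures identify metabolites whose responses track organism-level
properties:

* a four-way main-effects ANOVA on log2 fold-changes with the factors
  taxonomy group, habitat, cell-wall class and salt-tolerance class,
  using added-last (partial) sums of squares for the unbalanced design;
* a correlation screen of per-metabolite fold-changes against organism
  IC50, reporting Pearson's R together with the upper quartile x0.75 of
  absolute fold-changes as the effect-size axis.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import OrganismMeta, ValidationError, tolerance_class

ANOVA_FACTORS = ("taxonomy_group", "habitat", "cell_wall", "tolerance")


def organism_factor_table(metas: list[OrganismMeta]) -> pd.DataFrame:
    """Factor levels per organism, deriving the tolerance class from IC50."""
    rows = []
    for m in metas:
        rows.append(
            {
                "organism_id": m.organism_id,
                "taxonomy_group": m.taxonomy_group,
                "habitat": m.habitat,
                "cell_wall": m.cell_wall,
                "tolerance": tolerance_class(m) if not np.isnan(m.ic50) else None,
                "ic50": m.ic50,
            }
        )
    return pd.DataFrame(rows).set_index("organism_id")


# ---------------------------------------------------------------------------
# four-way ANOVA


@dataclass
class AnovaResult:
    metabolite_id: str
    p_values: dict[str, float]  # factor -> p (NaN when untestable)
    group_stats: dict[str, pd.DataFrame]  # factor -> (level x [mean, se, n])
    n_organisms: int
    selected_factors: set[str] = field(default_factory=set)


def _rss(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid), int(np.linalg.matrix_rank(x))


def fourway_anova(
    fc_ic50: pd.DataFrame,
    metas: list[OrganismMeta],
    factors=ANOVA_FACTORS,
) -> list[AnovaResult]:
    """Main-effects ANOVA of each metabolite's fold-changes across organisms.

    ``fc_ic50`` is a metabolite x organism matrix of log2 fold-changes at
    the high-stress level. Each metabolite is analysed complete-case; a
    factor with fewer than two populated levels for that metabolite is
    marked untestable (p = NaN). Factor p-values use added-last partial
    sums of squares against the full main-effects model.
    """
    table = organism_factor_table(metas)
    fc = pd.DataFrame(fc_ic50).astype(float)
    missing_meta = [o for o in fc.columns if o not in table.index]
    if missing_meta:
        raise ValidationError(f"organisms without metadata: {missing_meta}")
    cols = list(fc.columns)
    sub_table = table.loc[cols]
    # integer level codes per factor, -1 for missing metadata
    codes = {}
    levels_of = {}
    for f in factors:
        cat = pd.Categorical(sub_table[f])
        codes[f] = cat.codes.copy()
        levels_of[f] = list(cat.categories)
    meta_ok = np.all([codes[f] >= 0 for f in factors], axis=0)
    fc_arr = fc.to_numpy()
    results = []
    for mi, met in enumerate(fc.index):
        row = fc_arr[mi]
        mask = ~np.isnan(row) & meta_ok
        y = row[mask]
        n = int(mask.sum())
        p_values = {f: np.nan for f in factors}
        group_stats = {}
        testable = []
        for f in factors:
            cf = codes[f][mask]
            present = np.unique(cf)
            cnt = np.bincount(cf, minlength=len(levels_of[f]))[present]
            sums = np.bincount(cf, weights=y, minlength=len(levels_of[f]))[present]
            means = sums / cnt
            sq = np.bincount(cf, weights=y**2, minlength=len(levels_of[f]))[present]
            with np.errstate(invalid="ignore", divide="ignore"):
                var = (sq - cnt * means**2) / np.maximum(cnt - 1, 1)
                var[cnt < 2] = np.nan
                se = np.sqrt(np.maximum(var, 0) / cnt)
            group_stats[f] = pd.DataFrame(
                {"mean": means, "se": se, "n": cnt},
                index=[levels_of[f][i] for i in present],
            )
            if len(present) >= 2:
                testable.append(f)
        tss = float(np.sum((y - y.mean()) ** 2)) if n else 0.0
        if n >= 3 and testable and tss <= 1e-12 * max(1.0, float(np.sum(y**2))):
            # constant response: F = 0 for every testable factor
            for f in testable:
                p_values[f] = 1.0
        elif n >= 3 and testable:
            blocks = {}
            for f in testable:
                cf = codes[f][mask]
                present = np.unique(cf)
                blocks[f] = (cf[:, None] == present[None, 1:]).astype(float)
            intercept = np.ones((n, 1))
            x_full = np.hstack([intercept] + [blocks[f] for f in testable])
            rss_full, rank_full = _rss(x_full, y)
            df_err = n - rank_full
            if df_err > 0:
                for f in testable:
                    x_red = np.hstack(
                        [intercept] + [blocks[g] for g in testable if g != f]
                    )
                    rss_red, rank_red = _rss(x_red, y)
                    df_f = rank_full - rank_red
                    if df_f <= 0:
                        continue  # factor aliased with the others
                    num = (rss_red - rss_full) / df_f
                    den = rss_full / df_err
                    if den <= 0:
                        p_values[f] = 1.0 if num <= 0 else 0.0
                    else:
                        p_values[f] = float(stats.f.sf(num / den, df_f, df_err))
        res = AnovaResult(
            metabolite_id=str(met),
            p_values=p_values,
            group_stats=group_stats,
            n_organisms=n,
        )
        results.append(res)
    return results


def select_anova_hits(
    results: list[AnovaResult],
    p_cut: float = 0.01,
    fc_cut: float = 1.0,
    top_k: int = 40,
) -> tuple[dict[str, pd.DataFrame], int]:
    """Per-factor ranked hit lists and the size of their union.

    A metabolite is a hit for a factor when that factor's ANOVA p < p_cut
    and the largest |group mean fold-change| over the factor's levels
    exceeds fc_cut. Lists are sorted by ascending p and truncated to
    ``top_k`` for reporting; the union count is taken before truncation.
    """
    per_factor: dict[str, pd.DataFrame] = {}
    union: set[str] = set()
    factors = list(results[0].p_values) if results else []
    for f in factors:
        rows = []
        for res in results:
            p = res.p_values.get(f, np.nan)
            if np.isnan(p) or p >= p_cut:
                continue
            max_fc = float(res.group_stats[f]["mean"].abs().max())
            if max_fc > fc_cut:
                rows.append(
                    {
                        "metabolite_id": res.metabolite_id,
                        "p_value": p,
                        "max_abs_group_mean": max_fc,
                        "n_organisms": res.n_organisms,
                    }
                )
                res.selected_factors.add(f)
                union.add(res.metabolite_id)
        df = pd.DataFrame(
            rows, columns=["metabolite_id", "p_value", "max_abs_group_mean", "n_organisms"]
        ).sort_values(["p_value", "metabolite_id"]).head(top_k)
        per_factor[f] = df.reset_index(drop=True)
    return per_factor, len(union)


# ---------------------------------------------------------------------------
# tolerance-correlation screen


def upper_quartile(values) -> float:
    """x0.75: upper quartile by linear interpolation between order
    statistics at position 1 + 0.75 (n - 1)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) == 0:
        raise ValidationError("no values for quartile")
    return float(np.percentile(v, 75, method="linear"))


@dataclass
class ScreenResult:
    metabolite_id: str
    r: float
    x075: float
    n_detected: int
    hit_direction: str  # anticorrelating | correlating | none

    @property
    def is_hit(self) -> bool:
        return self.hit_direction != "none"


def tolerance_screen(
    fc_ic50: pd.DataFrame,
    ic50s: dict[str, float] | pd.Series,
    min_species: int = 10,
    r_cut: float = 0.5,
    x_cut: float = 1.0,
) -> list[ScreenResult]:
    """Correlate each metabolite's high-stress response with organism IC50.

    For each metabolite, Pearson's R between its log2 fold-changes and
    the organisms' IC50 values, together with x0.75 of |log2FC|, over the
    organisms where the metabolite was detected. Hits require detection
    in more than ``min_species`` organisms (strictly), x0.75 > x_cut and
    |R| > r_cut; sign of R decides correlating vs anticorrelating.
    Metabolites detected in fewer than 3 organisms are excluded.
    """
    ic50s = pd.Series(ic50s, dtype=float)
    fc = pd.DataFrame(fc_ic50).astype(float)
    missing = [o for o in fc.columns if o not in ic50s.index or np.isnan(ic50s[o])]
    if missing:
        raise ValidationError(f"organisms without IC50: {missing}")
    results = []
    for met, row in fc.iterrows():
        obs = row.dropna()
        n = len(obs)
        if n < 3:
            continue
        x = ic50s[obs.index].to_numpy()
        y = obs.to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            r = np.nan
        else:
            r = float(stats.pearsonr(x, y).statistic)
        x075 = upper_quartile(np.abs(y))
        direction = "none"
        if n > min_species and x075 > x_cut and abs(r) > r_cut:
            direction = "correlating" if r > 0 else "anticorrelating"
        results.append(
            ScreenResult(
                metabolite_id=str(met), r=r, x075=x075, n_detected=n,
                hit_direction=direction,
            )
        )
    return results


def screen_frame(results: list[ScreenResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metabolite_id": s.metabolite_id,
                "R": s.r,
                "x075": s.x075,
                "n_detected": s.n_detected,
                "hit_direction": s.hit_direction,
            }
            for s in results
        ]
    )
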