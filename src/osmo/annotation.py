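"""Accurate-mass ion annotation and polar/nonpolar extract merging.

Negative-mode flow-injection spectra contain deprotonated molecular ions
[M-H]- and their single-13C isotopologues [M-H, 1x12C->13C]-. Each
centroid m/z is matched within an absolute tolerance (default 0.005 Da)
against the expected ion m/z of every compound associated with the
profiled organism. Ambiguity (two or more candidate compounds for one
feature) is flagged and propagated, never auto-resolved.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CompoundLibrary, CompoundRecord, IonTable, ValidationError
from .masses import C13_C12_DELTA, PROTON_MASS

SPECIES_FORMS = ("[M-H]-", "[M-H]+13C")
DEFAULT_TOLERANCE = 0.005  # Da


def expected_mz(mass: float, species_form: str) -> float:
    """Expected ion m/z for a neutral monoisotopic mass.

    [M-H]- subtracts one proton; [M-H]+13C additionally carries one
    12C->13C substitution (+1.0033548 Da).
    """
    if mass <= 0:
        raise ValueError("neutral mass must be positive")
    if species_form == "[M-H]-":
        return mass - PROTON_MASS
    if species_form == "[M-H]+13C":
        return mass - PROTON_MASS + C13_C12_DELTA
    raise ValueError(f"unknown species form {species_form!r}")


@dataclass
class AnnotatedIon:
    """One m/z feature with its candidate compound assignments."""

    mz: float
    candidates: list[tuple[str, str, float]] = field(default_factory=list)
    # (compound_id, species_form, mass_error in Da), sorted by |mass_error|

    @property
    def ambiguous(self) -> bool:
        return len({cid for cid, _, _ in self.candidates}) >= 2

    @property
    def annotated(self) -> bool:
        return bool(self.candidates)


def annotate_ions(
    table: IonTable,
    lib: CompoundLibrary,
    organism_id: str,
    tolerance: float = DEFAULT_TOLERANCE,
) -> list[AnnotatedIon]:
    """Annotate every feature of an ion table against an organism's library.

    Only compounds associated with ``organism_id`` are considered. A
    feature matches a compound when |observed - expected| <= tolerance
    for either ion species; all matches are kept as candidates sorted by
    absolute mass error. Unmatched features are returned with an empty
    candidate list.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    sub = lib.subset_for_organism(organism_id)
    # expected m/z index over (compound, species form)
    exp_mz = []
    exp_meta = []
    for rec in sub:
        for form in SPECIES_FORMS:
            exp_mz.append(expected_mz(rec.neutral_monoisotopic_mass, form))
            exp_meta.append((rec.compound_id, form))
    exp_mz = np.asarray(exp_mz)
    order = np.argsort(exp_mz)
    exp_mz = exp_mz[order]
    exp_meta = [exp_meta[i] for i in order]

    out = []
    for mz in table.mz:
        lo = np.searchsorted(exp_mz, mz - tolerance, side="left")
        hi = np.searchsorted(exp_mz, mz + tolerance, side="right")
        cands = [
            (exp_meta[i][0], exp_meta[i][1], float(mz - exp_mz[i]))
            for i in range(lo, hi)
        ]
        cands.sort(key=lambda c: (abs(c[2]), c[0], c[1]))
        out.append(AnnotatedIon(mz=float(mz), candidates=cands))
    return out


def select_phase(record: CompoundRecord) -> str:
    """Extract phase supplying a compound's intensities: by octanol/water logP.

    Hydrophilic compounds (logP <= 0) are read from the polar extract,
    hydrophobic ones (logP > 0) from the nonpolar extract.
    """
    logp = record.logp_ow
    if logp is None or np.isnan(logp):
        raise ValidationError(f"{record.compound_id}: missing logP")
    return "polar" if logp <= 0 else "nonpolar"


@dataclass
class MetaboliteTable:
    """Metabolite-resolved intensities merged from the two extract phases.

    Each row is one annotated ion of one metabolite; several rows may
    share a metabolite id when different features annotate the same
    compound (duplicate names represent different ions of the same
    metabolite). ``meta`` carries provenance: source feature m/z, phase,
    species form and the ambiguity flag.
    """

    intensities: pd.DataFrame  # row_id x sample_id
    meta: pd.DataFrame  # row_id x (metabolite_id, name, mz, phase, species_form, ambiguous, is_osmoprotectant)
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.intensities.index.equals(self.meta.index):
            raise ValidationError("intensity and meta row indices differ")

    def rows_for(self, metabolite_id: str) -> pd.Index:
        return self.meta.index[self.meta["metabolite_id"] == metabolite_id]


def merge_extracts(
    polar: IonTable | None,
    nonpolar: IonTable | None,
    annotations: dict[str, list[AnnotatedIon]],
    lib: CompoundLibrary,
) -> MetaboliteTable:
    """Build a metabolite table by routing each compound to its logP phase.

    ``annotations`` maps phase name -> per-feature annotation list for
    the matching ion table. Compounds annotated only in the wrong phase
    are excluded. Every (compound, feature, species form) match in the
    selected phase becomes one output row.
    """
    tables = {"polar": polar, "nonpolar": nonpolar}
    rows = []
    data = []
    for phase, table in tables.items():
        if table is None:
            continue
        anns = annotations.get(phase, [])
        if len(anns) != table.n_features:
            raise ValidationError(
                f"{phase}: {len(anns)} annotations for {table.n_features} features"
            )
        for i, ann in enumerate(anns):
            for cid, form, err in ann.candidates:
                rec = lib[cid]
                if select_phase(rec) != phase:
                    continue
                row_id = f"{cid}@{ann.mz:.4f}{'+13C' if form.endswith('13C') else ''}"
                rows.append(
                    {
                        "row_id": row_id,
                        "metabolite_id": cid,
                        "name": rec.name,
                        "mz": ann.mz,
                        "phase": phase,
                        "species_form": form,
                        "mass_error": err,
                        "ambiguous": ann.ambiguous,
                        "is_osmoprotectant": rec.is_osmoprotectant,
                    }
                )
                data.append(table.intensities.iloc[i])
    if not rows:
        raise ValidationError("no metabolite annotated in either phase")
    meta = pd.DataFrame(rows).set_index("row_id")
    intensities = pd.DataFrame(data)
    intensities.index = meta.index
    designs = [t.design for t in tables.values() if t is not None]
    design = pd.concat(designs)
    design = design[~design.index.duplicated()]
    # duplicated row_id can occur if two features collapse to identical m/z text
    if meta.index.duplicated().any():
        meta = meta[~meta.index.duplicated()]
        intensities = intensities[~intensities.index.duplicated()]
    return MetaboliteTable(intensities=intensities, meta=meta, design=design)
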