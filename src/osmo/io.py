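"""Data model and file IO for the salt-stress metabolomics pipeline.

Tabular files are tab-separated UTF-8 with one header row and ``NA`` for
missing values. Readers validate on construction and never return a
partially built object.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .masses import monoisotopic_mass, parse_formula

STRESS_LEVELS = ("IC0", "IC10", "IC25", "IC50")
EXTRACT_PHASES = ("polar", "nonpolar")
NA_REP = "NA"


class ValidationError(ValueError):
    """An input file or object failed validation."""


# ---------------------------------------------------------------------------
# organism metadata


@dataclass
class OrganismMeta:
    """One analysed organism or cell line with its salt-tolerance phenotype.

    IC values are NaCl concentrations in mM; ``nan`` means not determined.
    """

    organism_id: str
    display_name: str = ""
    taxonomy_group: str = ""
    habitat: str = ""
    cell_wall: str = ""
    ic10: float = float("nan")
    ic25: float = float("nan")
    ic50: float = float("nan")
    n_bio_replicates: int = 4

    def __post_init__(self) -> None:
        ics = [self.ic10, self.ic25, self.ic50]
        known = [x for x in ics if not np.isnan(x)]
        if known != sorted(known):
            raise ValidationError(
                f"{self.organism_id}: IC10 <= IC25 <= IC50 violated: {ics}"
            )


def tolerance_class(meta: OrganismMeta | float) -> str:
    """Bin an organism by its IC50 into {low, medium, high} salt tolerance.

    IC50 < 500 mM NaCl is low, 500-1000 mM (inclusive on both ends) is
    medium, and above 1000 mM is high.
    """
    ic50 = meta.ic50 if isinstance(meta, OrganismMeta) else float(meta)
    if np.isnan(ic50):
        raise ValidationError("tolerance_class requires a determined IC50")
    if ic50 < 500.0:
        return "low"
    if ic50 <= 1000.0:
        return "medium"
    return "high"


def read_organism_table(path: str | Path) -> list[OrganismMeta]:
    df = pd.read_csv(path, sep="\t", na_values=[NA_REP], keep_default_na=False)
    required = {"organism_id", "taxonomy_group", "habitat", "cell_wall"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"organism table missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            OrganismMeta(
                organism_id=str(row["organism_id"]),
                display_name=str(row.get("display_name", row["organism_id"])),
                taxonomy_group=str(row["taxonomy_group"]),
                habitat=str(row["habitat"]),
                cell_wall=str(row["cell_wall"]),
                ic10=float(row.get("ic10", np.nan)) if not pd.isna(row.get("ic10", np.nan)) else np.nan,
                ic25=float(row.get("ic25", np.nan)) if not pd.isna(row.get("ic25", np.nan)) else np.nan,
                ic50=float(row.get("ic50", np.nan)) if not pd.isna(row.get("ic50", np.nan)) else np.nan,
                n_bio_replicates=int(row.get("n_bio_replicates", 4)),
            )
        )
    ids = [m.organism_id for m in out]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate organism_id in organism table")
    return out


def write_organism_table(metas: Iterable[OrganismMeta], path: str | Path) -> None:
    df = pd.DataFrame([dataclasses.asdict(m) for m in metas])
    df.to_csv(path, sep="\t", index=False, na_rep=NA_REP)


def load_reference_organisms() -> list[OrganismMeta]:
    """The bundled panel of the 16 reference organisms and cell lines."""
    with resources.as_file(resources.files("osmo.data") / "organisms.tsv") as p:
        return read_organism_table(p)


# ---------------------------------------------------------------------------
# sample design and ion tables


DESIGN_COLUMNS = [
    "sample_id",
    "organism_id",
    "stress_level",
    "extract_phase",
    "bio_replicate",
    "tech_replicate",
]


def _validate_design(design: pd.DataFrame) -> pd.DataFrame:
    missing = set(DESIGN_COLUMNS) - set(design.columns)
    if missing:
        raise ValidationError(f"design table missing columns: {sorted(missing)}")
    bad_level = set(design["stress_level"]) - set(STRESS_LEVELS)
    if bad_level:
        raise ValidationError(f"unknown stress levels: {sorted(bad_level)}")
    bad_phase = set(design["extract_phase"]) - set(EXTRACT_PHASES)
    if bad_phase:
        raise ValidationError(f"unknown extract phases: {sorted(bad_phase)}")
    key = design[["organism_id", "stress_level", "extract_phase", "bio_replicate", "tech_replicate"]]
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0].tolist()
        raise ValidationError(f"duplicate design tuple: {dup}")
    if design["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in design table")
    return design.set_index("sample_id", drop=False)


@dataclass
class IonTable:
    """A feature (m/z) x sample matrix of centroided ion intensities.

    ``mz`` holds one m/z value in Da per row of ``intensities``; the
    intensity columns are sample ids matching ``design``. Missing
    intensities are NaN.
    """

    mz: np.ndarray
    intensities: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        if self.mz.ndim != 1 or len(self.mz) != len(self.intensities):
            raise ValidationError("mz length must match intensity rows")
        if np.any(self.mz <= 0):
            raise ValidationError("m/z values must be strictly positive")
        if "sample_id" not in self.design.columns:
            raise ValidationError("design table missing sample_id")
        if self.design.index.name != "sample_id":
            self.design = _validate_design(self.design)
        unmatched = [c for c in self.intensities.columns if c not in self.design.index]
        if unmatched:
            raise ValidationError(f"intensity columns absent from design: {unmatched}")
        with np.errstate(invalid="ignore"):
            if (self.intensities.to_numpy(dtype=float) < 0).any():
                raise ValidationError("intensities must be non-negative")

    @property
    def n_features(self) -> int:
        return len(self.mz)

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)

    def design_for_samples(self) -> pd.DataFrame:
        return self.design.loc[self.samples]


def read_ion_table(path: str | Path, design_path: str | Path) -> IonTable:
    """Read an intensity matrix (first column ``mz``) and its design table."""
    df = pd.read_csv(path, sep="\t", na_values=[NA_REP], keep_default_na=False)
    if "mz" not in df.columns:
        raise ValidationError(f"{path}: first column must be 'mz'")
    design = pd.read_csv(design_path, sep="\t", na_values=[NA_REP], keep_default_na=False)
    design = _validate_design(design)
    sample_cols = [c for c in df.columns if c != "mz"]
    for col in sample_cols:
        if col not in design.index:
            raise ValidationError(f"{path}: column {col!r} has no design row")
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"{path}: non-numeric intensity at row {row}, column {col!r}"
            )
        df[col] = vals
    mz = pd.to_numeric(df["mz"], errors="coerce")
    if mz.isna().any():
        raise ValidationError(f"{path}: non-numeric m/z value")
    return IonTable(mz.to_numpy(), df[sample_cols], design)


def write_ion_table(table: IonTable, path: str | Path) -> None:
    out = table.intensities.copy()
    out.insert(0, "mz", table.mz)
    out.to_csv(path, sep="\t", index=False, na_rep=NA_REP, float_format="%.10g")


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.reset_index(drop=True) if design.index.name == "sample_id" else design
    design[DESIGN_COLUMNS].to_csv(path, sep="\t", index=False, na_rep=NA_REP)


# ---------------------------------------------------------------------------
# compound libraries


@dataclass
class CompoundRecord:
    compound_id: str
    name: str
    formula: dict[str, int]
    logp_ow: float
    organism_ids: frozenset[str] = field(default_factory=frozenset)
    is_osmoprotectant: bool = False
    neutral_monoisotopic_mass: float = field(init=False)

    def __post_init__(self) -> None:
        self.neutral_monoisotopic_mass = monoisotopic_mass(self.formula)
        if self.neutral_monoisotopic_mass <= 0:
            raise ValidationError(f"{self.compound_id}: non-positive mass")


class CompoundLibrary:
    """Compound records indexed by id and by neutral monoisotopic mass.

    The mass index is kept sorted so that annotation can query a +-tol
    window with binary search.
    """

    def __init__(self, records: Sequence[CompoundRecord]):
        ids = [r.compound_id for r in records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate compound ids: {dup}")
        self.records: list[CompoundRecord] = list(records)
        self._by_id = {r.compound_id: r for r in self.records}
        order = np.argsort([r.neutral_monoisotopic_mass for r in self.records])
        self._sorted = [self.records[i] for i in order]
        self._sorted_masses = np.array(
            [r.neutral_monoisotopic_mass for r in self._sorted]
        )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, compound_id: str) -> CompoundRecord:
        return self._by_id[compound_id]

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self._by_id

    def mass_window(self, mass: float, tol: float) -> list[CompoundRecord]:
        """All records with |neutral mass - mass| <= tol, by ascending mass."""
        lo = np.searchsorted(self._sorted_masses, mass - tol, side="left")
        hi = np.searchsorted(self._sorted_masses, mass + tol, side="right")
        return self._sorted[lo:hi]

    def organisms(self) -> set[str]:
        out: set[str] = set()
        for r in self.records:
            out |= set(r.organism_ids)
        return out

    def subset_for_organism(self, organism_id: str) -> "CompoundLibrary":
        if organism_id not in self.organisms():
            raise ValidationError(f"organism {organism_id!r} absent from library")
        return CompoundLibrary(
            [r for r in self.records if organism_id in r.organism_ids]
        )


def read_compound_library(path: str | Path) -> CompoundLibrary:
    df = pd.read_csv(path, sep="\t", na_values=[NA_REP], keep_default_na=False)
    required = {"compound_id", "formula", "logp"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"compound library missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        cid = str(row["compound_id"])
        try:
            formula = parse_formula(str(row["formula"]))
        except ValueError as exc:
            raise ValidationError(f"compound {cid!r}: {exc}") from exc
        orgs = row.get("organism_ids", "")
        org_set = frozenset(
            s for s in str(orgs).split(",") if s and not pd.isna(orgs)
        )
        records.append(
            CompoundRecord(
                compound_id=cid,
                name=str(row.get("name", cid)),
                formula=formula,
                logp_ow=float(row["logp"]),
                organism_ids=org_set,
                is_osmoprotectant=bool(int(row.get("is_osmoprotectant", 0))),
            )
        )
    return CompoundLibrary(records)


def write_compound_library(lib: CompoundLibrary, path: str | Path) -> None:
    rows = []
    for r in lib:
        formula = "".join(
            f"{el}{n if n > 1 else ''}" for el, n in sorted(r.formula.items())
        )
        rows.append(
            {
                "compound_id": r.compound_id,
                "name": r.name,
                "formula": formula,
                "logp": r.logp_ow,
                "organism_ids": ",".join(sorted(r.organism_ids)),
                "is_osmoprotectant": int(r.is_osmoprotectant),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep=NA_REP)


# ---------------------------------------------------------------------------
# alignments


def read_alignment(path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA file; all sequences must have equal length."""
    seqs: dict[str, str] = {}
    length = None
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        if length is None:
            length = len(s)
        elif len(s) != length:
            raise ValidationError(
                f"sequence {rec.id!r} has length {len(s)}, expected {length}"
            )
        seqs[rec.id] = s
    if not seqs:
        raise ValidationError(f"{path}: no sequences found")
    return seqs


def write_alignment(seqs: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")
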