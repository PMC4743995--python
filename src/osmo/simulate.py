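"""Synthetic salt-stress study generator with machine-readable ground truth.

Emulates the structure of the cross-species study: a panel of organisms
(default 16: twelve bacteria across four taxonomy groups, two yeasts,
two human cell lines) with log-uniform IC50 in 150-1500 mM NaCl, growth
curves under a 12-point salt gradient in duplicate, a compound library
with logP-routed extract phases, and two-phase ion tables with 4
(microbes) or 3 (human) biological x 2 technical replicates, log-normal
intensity noise and decoy features outnumbering true features 10:1.

Planted effect classes
----------------------
osmoprotectant-accumulation
    flagged compounds accumulate >= 1 log2 unit at IC50, graded 1/3 and
    2/3 of that at IC10/IC25.
species-specific
    one organism shifts a compound strongly; all others are unchanged.
factor-specific
    every organism in one level of one design factor shares an offset.
tolerance-correlated-positive / -negative
    the IC50-level log2 fold-change is a linear function of organism
    IC50 plus noise, calibrated to |Pearson R| ~ 0.8 and x0.75 ~ 1.5.
null
    baseline noise only.

All outputs are pure functions of (config, seed).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import expected_mz
from .dose_response import GrowthCurve
from .io import CompoundLibrary, CompoundRecord, IonTable, OrganismMeta

TAXONOMY_CYCLE = (
    "alpha-proteobacteria",
    "gamma-proteobacteria",
    "firmicutes",
    "actinobacteria",
    "fungi",
    "human",
)
HABITAT_CYCLE = ("free-living", "plant-associated", "animal-associated")
LEVEL_SCALE = {"IC0": 0.0, "IC10": 1.0 / 3.0, "IC25": 2.0 / 3.0, "IC50": 1.0}
STRESS_ORDER = ("IC0", "IC10", "IC25", "IC50")

# log2-scale replicate noise; CV on the linear scale -> sigma of ln -> /ln 2
_LN2 = float(np.log(2.0))


def _log2_sd_from_cv(cv: float) -> float:
    return float(np.sqrt(np.log(1.0 + cv**2)) / _LN2)


# ---------------------------------------------------------------------------
# trees


@dataclass
class TreeNode:
    """Minimal rooted tree: branch length above each node, named leaves."""

    name: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out

    def to_newick(self) -> str:
        def rec(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.10g}"
            inner = ",".join(rec(ch) for ch in node.children)
            return f"({inner}):{node.length:.10g}"

        if self.is_leaf:
            return f"{self.name};"
        inner = ",".join(rec(ch) for ch in self.children)
        return f"({inner});"

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Path lengths (sums of branch lengths) between all leaf pairs."""
        dist: dict[tuple[str, str], float] = {}

        def rec(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            maps = []
            for ch in node.children:
                m = {k: v + ch.length for k, v in rec(ch).items()}
                maps.append(m)
            for i in range(len(maps)):
                for j in range(i + 1, len(maps)):
                    for a, da in maps[i].items():
                        for b, db in maps[j].items():
                            key = (a, b) if a < b else (b, a)
                            dist[key] = da + db
            merged = {}
            for m in maps:
                merged.update(m)
            return merged

        rec(self)
        return dist


def random_coalescent_tree(
    labels: list[str], rng: np.random.Generator, total_height: float = 0.25
) -> TreeNode:
    """Random binary (Kingman coalescent) tree over labels, rescaled so the
    root sits at ``total_height`` expected substitutions per site."""
    nodes = [TreeNode(name=lb) for lb in labels]
    heights = [0.0] * len(nodes)
    h = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        h += rng.exponential(1.0 / (k * (k - 1) / 2.0))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = h - heights[i]
        b.length = h - heights[j]
        parent = TreeNode(children=[a, b])
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)] + [parent]
        heights = [hh for idx, hh in enumerate(heights) if idx not in (i, j)] + [h]
    root = nodes[0]
    scale = total_height / h if h > 0 else 1.0

    def rescale(node: TreeNode) -> None:
        node.length *= scale
        for ch in node.children:
            rescale(ch)

    rescale(root)
    root.length = 0.0
    return root


def simulate_alignment(
    tree: TreeNode, length: int, seed: int | np.random.Generator
) -> dict[str, str]:
    """Evolve aligned sequences along a tree under the Jukes-Cantor model.

    Each branch of length b substitutes a site with probability
    3/4 (1 - exp(-4b/3)), choosing uniformly among the three other
    bases — the exact JC transition kernel.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    bases = np.array(list("ACGT"))
    out: dict[str, str] = {}

    def rec(node: TreeNode, seq: np.ndarray) -> None:
        if node.length > 0:
            p_diff = 0.75 * (1.0 - np.exp(-4.0 * node.length / 3.0))
            hit = rng.random(length) < p_diff
            if hit.any():
                seq = seq.copy()
                shift = rng.integers(1, 4, size=int(hit.sum()))
                seq[hit] = (seq[hit] + shift) % 4
        if node.is_leaf:
            out[node.name] = "".join(bases[seq])
        else:
            for ch in node.children:
                rec(ch, seq)

    root_seq = rng.integers(0, 4, size=length)
    rec(tree, root_seq)
    return out


def simulate_tree_structured_responses(
    tree: TreeNode,
    n_metabolites: int,
    seed: int | np.random.Generator,
    sigma_per_unit: float = 3.0,
    noise_sd: float = 0.1,
) -> pd.DataFrame:
    """Brownian-motion fold-change vectors diverging along a tree.

    Each branch adds independent N(0, sigma_per_unit**2 * length) to every
    metabolite, so organisms separated by longer paths respond more
    differently; ``noise_sd`` adds tip-level measurement noise.
    Returns an organism x metabolite matrix.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    rows: dict[str, np.ndarray] = {}

    def rec(node: TreeNode, value: np.ndarray) -> None:
        if node.length > 0:
            value = value + rng.normal(
                0.0, sigma_per_unit * np.sqrt(node.length), size=n_metabolites
            )
        if node.is_leaf:
            rows[node.name] = value + rng.normal(0.0, noise_sd, size=n_metabolites)
        else:
            for ch in node.children:
                rec(ch, value)

    rec(tree, np.zeros(n_metabolites))
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Registry of everything the generator planted."""

    organisms: dict[str, dict]  # organism_id -> true k, h, mu0, ic10/25/50
    effects: list[dict] = field(default_factory=list)
    tree_newick: str = ""

    def effects_of_class(self, effect_class: str) -> list[dict]:
        return [e for e in self.effects if e["effect_class"] == effect_class]

    def metabolites_of_class(self, effect_class: str) -> set[str]:
        return {e["metabolite_id"] for e in self.effects_of_class(effect_class)}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "organisms": self.organisms,
                    "effects": self.effects,
                    "tree_newick": self.tree_newick,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            organisms=d["organisms"],
            effects=d["effects"],
            tree_newick=d["tree_newick"],
        )


# ---------------------------------------------------------------------------
# organism panel


def simulate_panel(
    n_organisms: int = 16,
    seed: int | np.random.Generator = 0,
    ic50_range: tuple[float, float] = (150.0, 1500.0),
) -> tuple[list[OrganismMeta], GroundTruth]:
    """Random organism panel with true Hill dose-response parameters.

    IC50 is drawn log-uniformly over ``ic50_range`` (defaults spanning the
    most sensitive human line at 150 mM to the most tolerant bacterium at
    1500 mM); taxonomy groups, habitats and cell-wall classes cycle
    through their levels so every factor is populated.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    lo, hi = ic50_range
    metas = []
    organisms: dict[str, dict] = {}
    for i in range(n_organisms):
        group = TAXONOMY_CYCLE[i % len(TAXONOMY_CYCLE)]
        # habitat and cell wall drawn independently of taxonomy (apart from
        # the human cell lines) so every factor keeps its own degrees of
        # freedom in the four-way main-effects model
        if group == "human":
            habitat = "animal-associated"
            wall = "none"
        else:
            habitat = HABITAT_CYCLE[int(rng.integers(len(HABITAT_CYCLE)))]
            wall = "thin" if rng.random() < 0.5 else "thick"
        ic50 = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        h = float(rng.uniform(1.5, 4.0))
        k = ic50  # three-parameter Hill: IC50 equals k
        ic10 = k * (1.0 / 9.0) ** (1.0 / h)
        ic25 = k * (1.0 / 3.0) ** (1.0 / h)
        mu0 = float(rng.uniform(0.3, 0.9))
        org = f"org{i:02d}"
        metas.append(
            OrganismMeta(
                organism_id=org,
                display_name=f"Synthetic organism {i}",
                taxonomy_group=group,
                habitat=habitat,
                cell_wall=wall,
                ic10=ic10,
                ic25=ic25,
                ic50=ic50,
                n_bio_replicates=3 if group == "human" else 4,
            )
        )
        organisms[org] = {
            "k": k,
            "h": h,
            "mu0": mu0,
            "ic10": ic10,
            "ic25": ic25,
            "ic50": ic50,
        }
    return metas, GroundTruth(organisms=organisms)


# ---------------------------------------------------------------------------
# growth curves


def simulate_growth(
    metas: list[OrganismMeta],
    truth: GroundTruth,
    conc_grid: np.ndarray | None = None,
    n_replicates: int = 2,
    noise_sd: float = 0.02,
    seed: int | np.random.Generator = 0,
    t_max: float = 24.0,
    dt: float = 1.0 / 6.0,  # 10-min sampling
) -> dict[str, list[GrowthCurve]]:
    """Logistic growth curves with Hill-inhibited rates, in duplicate.

    The default concentration grid is an unstressed control plus twelve
    salt concentrations log-spaced over 50-2500 mM; observation noise is
    multiplicative log-normal with the given ln-scale SD.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    if conc_grid is None:
        conc_grid = np.concatenate([[0.0], np.geomspace(50.0, 2500.0, 12)])
    times = np.arange(0.0, t_max + dt / 2, dt)
    x0, cap = 0.05, 2.0
    out: dict[str, list[GrowthCurve]] = {}
    for meta in metas:
        p = truth.organisms[meta.organism_id]
        curves = []
        for conc in conc_grid:
            rate = p["mu0"] / (1.0 + (conc / p["k"]) ** p["h"]) if conc > 0 else p["mu0"]
            for _ in range(n_replicates):
                # exponential growth capped at the carrying capacity; the
                # pre-cap phase has exactly the Hill-inhibited specific rate
                x = np.minimum(x0 * np.exp(rate * times), cap)
                if noise_sd > 0:
                    x = x * np.exp(rng.normal(0.0, noise_sd, size=len(times)))
                curves.append(GrowthCurve(times=times, values=x, salt_conc=float(conc)))
        out[meta.organism_id] = curves
    return out


# ---------------------------------------------------------------------------
# compound library


_AMINO_SKELETONS = [
    # (C, H, N, O, S) ranges loosely covering primary-metabolite space
    ((2, 12), (4, 22), (0, 3), (1, 8), (0, 1)),
]


def simulate_library(
    organism_ids: list[str],
    n_compounds: int = 120,
    seed: int | np.random.Generator = 0,
    frac_polar: float = 0.75,
    n_osmoprotectants: int = 12,
    min_null_organisms: int = 8,
) -> CompoundLibrary:
    """Random compound library with unique formulas and logP-routed phases.

    Planted-effect compounds must be detectable in every organism, so the
    first ``n_osmoprotectants + 36`` compounds are associated with the
    full panel; the remainder get random subsets of >= min_null_organisms
    organisms, creating realistic variation in detection counts.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    (c_rng, h_rng, n_rng, o_rng, s_rng) = _AMINO_SKELETONS[0]
    records = []
    seen_formulas: set[tuple] = set()
    n_full = min(n_compounds, n_osmoprotectants + 36)
    attempts = 0
    while len(records) < n_compounds and attempts < 100 * n_compounds:
        attempts += 1
        c = int(rng.integers(*c_rng))
        h = int(rng.integers(max(c // 2, h_rng[0]), 2 * c + 3))
        nn = int(rng.integers(*n_rng))
        o = int(rng.integers(*o_rng))
        s = int(rng.integers(s_rng[0], s_rng[1] + 1))
        key = (c, h, nn, o, s)
        if key in seen_formulas:
            continue
        seen_formulas.add(key)
        formula = {"C": c, "H": h}
        if nn:
            formula["N"] = nn
        if o:
            formula["O"] = o
        if s:
            formula["S"] = s
        i = len(records)
        polar = rng.random() < frac_polar
        logp = float(rng.uniform(-4.0, 0.0)) if polar else float(rng.uniform(0.01, 6.0))
        if i < n_full or len(organism_ids) <= min_null_organisms:
            orgs = frozenset(organism_ids)
        else:
            size = int(rng.integers(min_null_organisms, len(organism_ids) + 1))
            orgs = frozenset(
                rng.choice(organism_ids, size=size, replace=False).tolist()
            )
        records.append(
            CompoundRecord(
                compound_id=f"met{i:04d}",
                name=f"synthetic compound {i}",
                formula=formula,
                logp_ow=logp,
                organism_ids=orgs,
                is_osmoprotectant=i < n_osmoprotectants,
            )
        )
    return CompoundLibrary(records)


# ---------------------------------------------------------------------------
# ion tables


@dataclass
class SimulationConfig:
    """Generator settings; the defaults are the study conditions."""

    n_organisms: int = 16
    n_compounds: int = 120
    n_osmoprotectants: int = 12
    n_species_specific: int = 4
    n_factor_specific: int = 8
    n_tolerance_pos: int = 6
    n_tolerance_neg: int = 6
    cv_bio: float = 0.20  # biological replicate coefficient of variation
    cv_tech: float = 0.10  # technical replicate CV
    mass_jitter: float = 0.004  # Da, strictly inside the 0.005 Da tolerance
    decoy_ratio: float = 10.0  # decoy features per true feature
    tolerance_slope: float = 2.4  # log2FC span across the IC50 range
    tolerance_intercept: float = 0.3
    tolerance_noise_sd: float = 0.45
    isotopologue_fraction: float = 0.2
    baseline_log2_mean: float = 14.0
    baseline_log2_sd: float = 2.0


def _plant_effects(
    lib: CompoundLibrary,
    metas: list[OrganismMeta],
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> list[dict]:
    """Assign effect classes to compounds and draw their parameters."""
    org_ids = [m.organism_id for m in metas]
    ic50 = {m.organism_id: m.ic50 for m in metas}
    lo = min(ic50.values())
    hi = max(ic50.values())
    span = hi - lo if hi > lo else 1.0
    compounds = [r.compound_id for r in lib]
    effects: list[dict] = []
    idx = 0

    for _ in range(cfg.n_osmoprotectants):
        cid = compounds[idx]
        idx += 1
        amp = {o: float(rng.uniform(1.2, 3.0)) for o in org_ids}
        effects.append(
            {"metabolite_id": cid, "effect_class": "osmoprotectant-accumulation",
             "params": {"amplitude": amp}}
        )
    for sign, count in (("positive", cfg.n_tolerance_pos), ("negative", cfg.n_tolerance_neg)):
        s = 1.0 if sign == "positive" else -1.0
        for _ in range(count):
            cid = compounds[idx]
            idx += 1
            fc = {}
            for o in org_ids:
                z = (ic50[o] - lo) / span
                fc[o] = float(
                    s * (cfg.tolerance_intercept + cfg.tolerance_slope * z)
                    + rng.normal(0.0, cfg.tolerance_noise_sd)
                )
            effects.append(
                {"metabolite_id": cid,
                 "effect_class": f"tolerance-correlated-{sign}",
                 "params": {"fc_ic50": fc}}
            )
    factors = ("taxonomy_group", "habitat", "cell_wall", "tolerance")
    from .io import tolerance_class

    factor_levels = {
        "taxonomy_group": sorted({m.taxonomy_group for m in metas}),
        "habitat": sorted({m.habitat for m in metas}),
        "cell_wall": sorted({m.cell_wall for m in metas}),
        "tolerance": sorted({tolerance_class(m) for m in metas}),
    }
    def _members(factor: str, level: str) -> list[str]:
        return [
            m.organism_id
            for m in metas
            if (tolerance_class(m) if factor == "tolerance" else getattr(m, factor))
            == level
        ]

    for j in range(cfg.n_factor_specific):
        cid = compounds[idx]
        idx += 1
        factor = factors[j % len(factors)]
        # plant only on identifiable levels: the human cell lines form both
        # the taxonomy "human" group and the cell-wall "none" class, so an
        # offset there cannot be attributed to one factor; levels also need
        # at least two member organisms for any power at P < 0.01
        candidates = [
            lv for lv in factor_levels[factor]
            if lv not in ("none", "human") and len(_members(factor, lv)) >= 2
        ]
        if not candidates:
            candidates = [
                lv for lv in factor_levels[factor] if len(_members(factor, lv)) >= 2
            ] or list(factor_levels[factor])
        level = candidates[int(rng.integers(len(candidates)))]
        amp = float(rng.choice([-1.0, 1.0]) * rng.uniform(2.5, 3.5))
        members = _members(factor, level)
        effects.append(
            {"metabolite_id": cid, "effect_class": "factor-specific",
             "params": {"factor": factor, "level": level, "amplitude": amp,
                        "organisms": members}}
        )
    for _ in range(cfg.n_species_specific):
        cid = compounds[idx]
        idx += 1
        org = org_ids[int(rng.integers(len(org_ids)))]
        amp = float(rng.choice([-1.0, 1.0]) * rng.uniform(2.0, 4.0))
        effects.append(
            {"metabolite_id": cid, "effect_class": "species-specific",
             "params": {"organism": org, "amplitude": amp}}
        )
    for cid in compounds[idx:]:
        effects.append({"metabolite_id": cid, "effect_class": "null", "params": {}})
    return effects


def simulate_ion_tables(
    metas: list[OrganismMeta],
    lib: CompoundLibrary,
    cfg: SimulationConfig | None = None,
    seed: int | np.random.Generator = 0,
    truth: GroundTruth | None = None,
) -> tuple[IonTable, IonTable, GroundTruth]:
    """Two-phase ion tables with planted effects and decoy features.

    Intensities are log-normal around per-(compound, organism) baselines;
    planted effects shift stress-level means on the log2 scale (graded
    1/3, 2/3, 1 over IC10/IC25/IC50 except tolerance-correlated effects,
    whose IC50-level fold-change is drawn explicitly and graded the same
    way). Features sit at the expected [M-H]- and 13C-isotopologue m/z
    plus uniform jitter within +-mass_jitter; decoy features match no
    library mass within 0.006 Da.
    """
    cfg = cfg or SimulationConfig()
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    if truth is None:
        truth = GroundTruth(organisms={m.organism_id: {"ic50": m.ic50} for m in metas})
    effects = _plant_effects(lib, metas, cfg, rng)
    truth.effects = effects
    effect_by_met = {e["metabolite_id"]: e for e in effects}

    org_ids = [m.organism_id for m in metas]
    n_bio = {m.organism_id: m.n_bio_replicates for m in metas}
    s_bio = _log2_sd_from_cv(cfg.cv_bio)
    s_tech = _log2_sd_from_cv(cfg.cv_tech)

    # per-compound per-organism baseline log2 intensity; NaN when absent
    compounds = list(lib)
    base = {}
    for rec in compounds:
        row = {}
        for o in org_ids:
            row[o] = (
                rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd)
                if o in rec.organism_ids
                else np.nan
            )
        base[rec.compound_id] = row

    def effect_fc(cid: str, org: str, level: str) -> float:
        e = effect_by_met[cid]
        scale = LEVEL_SCALE[level]
        cls = e["effect_class"]
        if cls == "null" or scale == 0.0:
            return 0.0
        p = e["params"]
        if cls == "osmoprotectant-accumulation":
            return p["amplitude"][org] * scale
        if cls.startswith("tolerance-correlated"):
            return p["fc_ic50"][org] * scale
        if cls == "factor-specific":
            return p["amplitude"] * scale if org in p["organisms"] else 0.0
        if cls == "species-specific":
            return p["amplitude"] * scale if org == p["organism"] else 0.0
        raise ValueError(cls)

    tables = {}
    for phase in ("polar", "nonpolar"):
        phase_compounds = [
            r for r in compounds
            if (r.logp_ow <= 0) == (phase == "polar")
        ]
        # sample design for this phase
        design_rows = []
        for o in org_ids:
            for level in STRESS_ORDER:
                for b in range(1, n_bio[o] + 1):
                    for t in (1, 2):
                        design_rows.append(
                            {
                                "sample_id": f"{o}_{level}_b{b}_t{t}_{phase}",
                                "organism_id": o,
                                "stress_level": level,
                                "extract_phase": phase,
                                "bio_replicate": b,
                                "tech_replicate": t,
                            }
                        )
        design = pd.DataFrame(design_rows)
        sample_ids = design["sample_id"].tolist()

        # true features: per compound, [M-H]- and 13C rows
        mz_list = []
        rows = []
        for rec in phase_compounds:
            for form, frac in (
                ("[M-H]-", 1.0),
                ("[M-H]+13C", cfg.isotopologue_fraction),
            ):
                mz = expected_mz(rec.neutral_monoisotopic_mass, form) + rng.uniform(
                    -cfg.mass_jitter, cfg.mass_jitter
                )
                mz_list.append(mz)
                rows.append((rec.compound_id, frac))

        n_true = len(mz_list)
        n_pc = len(phase_compounds)
        n_cols = len(sample_ids)
        org_pos = {o: i for i, o in enumerate(org_ids)}
        level_pos = {lv: i for i, lv in enumerate(STRESS_ORDER)}
        o_idx = design["organism_id"].map(org_pos).to_numpy()
        l_idx = design["stress_level"].map(level_pos).to_numpy()
        b_idx = design["bio_replicate"].to_numpy() - 1
        max_bio = max(n_bio.values())

        base_mat = np.array(
            [[base[r.compound_id][o] for o in org_ids] for r in phase_compounds]
        )  # (n_pc, n_org)
        eff = np.zeros((n_pc, len(org_ids), len(STRESS_ORDER)))
        for ci, rec in enumerate(phase_compounds):
            for oi, o in enumerate(org_ids):
                for li, level in enumerate(STRESS_ORDER):
                    eff[ci, oi, li] = effect_fc(rec.compound_id, o, level)
        # row order: compound-major, (mono, 13C)-minor — matches mz_list
        fracs = np.array([1.0, cfg.isotopologue_fraction])
        m_rows = (
            base_mat[:, None, :, None]
            + eff[:, None, :, :]
            + np.log2(fracs)[None, :, None, None]
        ).reshape(n_true, len(org_ids), len(STRESS_ORDER))
        bio_noise = rng.normal(
            0.0, s_bio, size=(n_true, len(org_ids), len(STRESS_ORDER), max_bio)
        )
        log2v = (
            m_rows[:, o_idx, l_idx]
            + bio_noise[:, o_idx, l_idx, b_idx]
            + rng.normal(0.0, s_tech, size=(n_true, n_cols))
        )
        intens = 2.0**log2v
        absent_rows = np.repeat(np.isnan(base_mat), 2, axis=0)  # (n_true, n_org)
        intens[absent_rows[:, o_idx]] = np.nan

        # decoy features: match nothing within 0.006 Da
        all_expected = np.sort(
            np.array(
                [
                    expected_mz(r.neutral_monoisotopic_mass, f)
                    for r in compounds
                    for f in ("[M-H]-", "[M-H]+13C")
                ]
            )
        )
        n_decoys = int(round(cfg.decoy_ratio * n_true))
        decoy_mz = []
        while len(decoy_mz) < n_decoys:
            cand = rng.uniform(50.0, 1000.0, size=n_decoys)
            pos = np.searchsorted(all_expected, cand)
            near = np.minimum(
                np.abs(cand - all_expected[np.clip(pos, 0, len(all_expected) - 1)]),
                np.abs(cand - all_expected[np.clip(pos - 1, 0, len(all_expected) - 1)]),
            )
            decoy_mz.extend(cand[near > 0.006].tolist())
        decoy_mz = np.array(decoy_mz[:n_decoys])
        decoy_base = rng.normal(12.0, 1.5, size=n_decoys)
        decoy_intens = 2.0 ** (
            decoy_base[:, None]
            + rng.normal(0.0, s_bio + s_tech, size=(n_decoys, len(sample_ids)))
        )

        mz_all = np.concatenate([np.array(mz_list), decoy_mz])
        data = np.vstack([intens, decoy_intens])
        order = np.argsort(mz_all)
        table = IonTable(
            mz=mz_all[order],
            intensities=pd.DataFrame(
                data[order], columns=sample_ids
            ),
            design=design,
        )
        tables[phase] = table
    return tables["polar"], tables["nonpolar"], truth


# ---------------------------------------------------------------------------
# whole-study convenience


@dataclass
class StudyBundle:
    metas: list[OrganismMeta]
    truth: GroundTruth
    library: CompoundLibrary
    polar: IonTable
    nonpolar: IonTable
    growth: dict[str, list[GrowthCurve]] | None = None
    alignment: dict[str, str] | None = None


def simulate_study(
    cfg: SimulationConfig | None = None,
    seed: int = 0,
    with_growth: bool = True,
    with_alignment: bool = True,
    alignment_length: int = 1500,
) -> StudyBundle:
    """One full synthetic study: panel, library, ion tables, growth, 16S."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(seed)
    metas, truth = simulate_panel(cfg.n_organisms, rng)
    lib = simulate_library(
        [m.organism_id for m in metas],
        n_compounds=cfg.n_compounds,
        seed=rng,
        n_osmoprotectants=cfg.n_osmoprotectants,
    )
    polar, nonpolar, truth = simulate_ion_tables(metas, lib, cfg, rng, truth)
    growth = simulate_growth(metas, truth, seed=rng) if with_growth else None
    alignment = None
    if with_alignment:
        tree = random_coalescent_tree([m.organism_id for m in metas], rng)
        truth.tree_newick = tree.to_newick()
        alignment = simulate_alignment(tree, alignment_length, rng)
    return StudyBundle(
        metas=metas,
        truth=truth,
        library=lib,
        polar=polar,
        nonpolar=nonpolar,
        growth=growth,
        alignment=alignment,
    )
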