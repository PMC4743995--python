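"""Normalisation, fold-changes, t-tests, Storey q-values, differential calls.

The differential workflow per organism: quantile-normalise intensities
within each extract phase, average technical replicates into their
biological replicate, compute log2 fold-changes of each stressed level
against the unstressed control, test each metabolite per level with a
pooled-variance two-sample t-test, and estimate q-values over the whole
organism-level family (all metabolites x all stress levels) with the
Storey-Tibshirani spline estimator of the null proportion pi0. A record
is differential at a level when |log2FC| >= 1 and q < 0.05; a metabolite
is differential for an organism when any level qualifies.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, stats

from .annotation import MetaboliteTable
from .io import ValidationError

STRESSED_LEVELS = ("IC10", "IC25", "IC50")


# ---------------------------------------------------------------------------
# quantile normalisation


def quantile_normalize(matrix) -> pd.DataFrame:
    """Force all sample columns onto the mean empirical distribution.

    Each column's sorted values are replaced by the across-column mean of
    order statistics; ties within a column receive the mean of the target
    values of their tied ranks. Columns with missing entries are mapped
    through quantile interpolation onto the same reference distribution.
    """
    df = pd.DataFrame(matrix).astype(float)
    if df.shape[1] < 2:
        raise ValidationError("quantile normalization needs >= 2 samples")
    n = df.shape[0]
    counts = df.notna().sum(axis=0)
    if (counts == 0).any():
        bad = list(df.columns[counts == 0])
        raise ValidationError(f"all-missing columns: {bad}")

    grid = np.linspace(0.0, 1.0, n)
    ref = np.zeros(n)
    for col in df.columns:
        v = np.sort(df[col].dropna().to_numpy())
        if len(v) == n:
            ref += v
        else:
            ref += np.interp(grid, np.linspace(0.0, 1.0, len(v)), v)
    ref /= df.shape[1]

    out = df.copy()
    for col in df.columns:
        v = df[col].to_numpy()
        ok = ~np.isnan(v)
        m = ok.sum()
        order = np.argsort(v[ok], kind="stable")
        if m == n:
            targets = ref
        else:
            targets = np.interp(np.linspace(0.0, 1.0, m), grid, ref)
        # average target values over tied ranks
        sv = v[ok][order]
        _, inv, cnt = np.unique(sv, return_inverse=True, return_counts=True)
        tie_means = np.bincount(inv, weights=targets) / cnt
        assigned = np.empty(m)
        assigned[order] = tie_means[inv]
        res = np.full(n, np.nan)
        res[ok] = assigned
        out[col] = res
    return out


# ---------------------------------------------------------------------------
# replicate handling and fold-changes


def average_technical_replicates(
    intensities: pd.DataFrame, design: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average technical replicates into their biological replicate.

    Returns (matrix, bio_design) where columns are one per
    (organism, stress, phase, bio_replicate) combination.
    """
    if design.index.name != "sample_id":
        design = design.set_index("sample_id", drop=False)
    design = design.loc[[c for c in intensities.columns if c in design.index]]
    if design.empty:
        raise ValidationError("no intensity columns found in the design table")
    keys = ["organism_id", "stress_level", "extract_phase", "bio_replicate"]
    groups = design.groupby(keys, sort=True, observed=True)
    cols = {}
    rows = []
    for key, sub in groups:
        bio_id = "|".join(str(k) for k in key)
        cols[bio_id] = intensities[sub.index.tolist()].mean(axis=1)
        rows.append(dict(zip(keys, key), bio_id=bio_id))
    matrix = pd.DataFrame(cols)
    bio_design = pd.DataFrame(rows).set_index("bio_id")
    return matrix, bio_design


@dataclass
class FoldChangeRecord:
    metabolite_id: str
    organism_id: str
    stress_level: str
    log2fc: float
    p_value: float
    q_value: float = np.nan
    differential: bool = False


def two_sample_test(a, b) -> tuple[float, float]:
    """Two-sided pooled-variance (Student) two-sample t-test.

    Zero variance in both groups with equal means yields (0, 1) by
    convention; fewer than two values per group is an error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs >= 2 values")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def log2_fold_changes(
    metab: MetaboliteTable | pd.DataFrame,
    design: pd.DataFrame | None = None,
    levels=STRESSED_LEVELS,
) -> pd.DataFrame:
    """Per metabolite/organism/stress-level log2 fold-change and t-test p.

    Technical replicates are first averaged into biological replicates;
    the fold-change is log2(mean stressed) - log2(mean control), and the
    t-test compares log2 biological-replicate intensities of the stressed
    level against the unstressed control. Non-positive means produce NaN
    fold-changes excluded from testing.
    """
    if isinstance(metab, MetaboliteTable):
        intensities, design = metab.intensities, metab.design
    else:
        if design is None:
            raise ValidationError("design required with a raw matrix")
        intensities = metab
    matrix, bio_design = average_technical_replicates(intensities, design)
    frames = []
    for organism in sorted(bio_design["organism_id"].unique()):
        sub = bio_design[bio_design["organism_id"] == organism]
        ctrl_cols = list(sub.index[sub["stress_level"] == "IC0"])
        if not ctrl_cols:
            raise ValidationError(f"{organism}: no IC0 control samples")
        ctrl = matrix[ctrl_cols].to_numpy()
        for level in levels:
            lev_cols = list(sub.index[sub["stress_level"] == level])
            if not lev_cols:
                continue
            stressed = matrix[lev_cols].to_numpy()
            with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mean_s = np.nanmean(stressed, axis=1)
                mean_c = np.nanmean(ctrl, axis=1)
                fc = np.log2(mean_s) - np.log2(mean_c)
            valid = (mean_s > 0) & (mean_c > 0)
            fc[~valid] = np.nan
            p = _pooled_t_rows(
                np.log2(np.where(stressed > 0, stressed, np.nan)),
                np.log2(np.where(ctrl > 0, ctrl, np.nan)),
            )
            p[~valid] = np.nan
            frames.append(
                pd.DataFrame(
                    {
                        "metabolite_id": matrix.index,
                        "organism_id": organism,
                        "stress_level": level,
                        "log2fc": fc,
                        "p_value": p,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def _pooled_t_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise two-sided pooled-variance t-test p-values.

    NaN entries are ignored; rows with fewer than two values in either
    group get NaN. Matches two_sample_test, including the p = 1
    convention for degenerate equal-constant rows.
    """
    na = np.sum(~np.isnan(a), axis=1)
    nb = np.sum(~np.isnan(b), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ma = np.nanmean(np.where(np.isnan(a), np.nan, a), axis=1)
        mb = np.nanmean(b, axis=1)
        va = np.nanvar(a, axis=1, ddof=1)
        vb = np.nanvar(b, axis=1, ddof=1)
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        t = (ma - mb) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        p = 2.0 * stats.t.sf(np.abs(t), df=np.maximum(df, 1))
    ok = (na >= 2) & (nb >= 2)
    p[~ok] = np.nan
    degenerate = ok & (sp2 == 0)
    p[degenerate & (ma == mb)] = 1.0
    p[degenerate & (ma != mb)] = 0.0
    return p


# ---------------------------------------------------------------------------
# Storey-Tibshirani q-values


def qvalues(p, lambdas=None, pi0: float | None = None) -> np.ndarray:
    """Storey-Tibshirani q-values for a family of p-values.

    pi0 (the null proportion) is estimated by evaluating
    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on the grid
    lambda = 0, 0.05, ..., 0.90, fitting a smoothing cubic spline and
    reading it off at lambda = 0.90, clamped to (0, 1]. Pass ``pi0=1`` to
    reduce to Benjamini-Hochberg. q-values are monotone from the largest
    p downward, so ordering is preserved.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    if pi0 is None:
        if m < 10:
            raise ValidationError("need >= 10 p-values for spline pi0 estimation")
        if lambdas is None:
            lambdas = np.arange(0.0, 0.9001, 0.05)
        lambdas = np.asarray(lambdas, dtype=float)
        pi0_lam = np.array(
            [(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas]
        )
        tck = interpolate.splrep(lambdas, pi0_lam, k=3)
        pi0 = float(interpolate.splev(lambdas.max(), tck))
        pi0 = min(max(pi0, 1.0 / m), 1.0)
    if not 0 < pi0 <= 1:
        raise ValidationError("pi0 must lie in (0, 1]")
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_differential(
    records: pd.DataFrame, fc_threshold: float = 1.0, alpha: float = 0.05
) -> pd.DataFrame:
    """Attach q-values and differential flags to fold-change records.

    The multiple-testing family is all tests within one organism (all
    metabolites x all stress levels). A record is differential when
    |log2fc| >= fc_threshold and q < alpha; ``differential_any`` marks
    (metabolite, organism) pairs flagged at any level.
    """
    out = records.copy()
    out["q_value"] = np.nan
    for organism in out["organism_id"].unique():
        mask = (out["organism_id"] == organism) & out["p_value"].notna()
        if mask.sum() == 0:
            continue
        p = out.loc[mask, "p_value"].to_numpy()
        pi0 = None if len(p) >= 10 else 1.0
        out.loc[mask, "q_value"] = qvalues(p, pi0=pi0)
    out["differential"] = (
        (out["log2fc"].abs() >= fc_threshold) & (out["q_value"] < alpha)
    ).fillna(False)
    any_flag = out.groupby(["metabolite_id", "organism_id"], sort=False)[
        "differential"
    ].transform("any")
    out["differential_any"] = any_flag
    return out


# ---------------------------------------------------------------------------
# cross-species baseline Z-scores


def baseline_zscores(
    metab_by_organism: pd.DataFrame, log_scale: bool = True, min_organisms: int = 3
) -> pd.DataFrame:
    """Z-scores of unstressed (IC0) abundances of each metabolite across organisms.

    Input: metabolite x organism matrix of organism-mean IC0 abundances.
    Z = (abundance - across-organism mean) / across-organism sample SD,
    computed on log2 abundances by default. Metabolites seen in fewer
    than ``min_organisms`` organisms are dropped; zero-variance rows get
    Z = 0 and are flagged. Entries with |Z| < 1 are tagged ``small``.
    """
    df = pd.DataFrame(metab_by_organism).astype(float)
    if log_scale:
        with np.errstate(divide="ignore"):
            df = np.log2(df.where(df > 0))
    enough = df.notna().sum(axis=1) >= min_organisms
    df = df[enough]
    mean = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1)
    z = df.sub(mean, axis=0).div(sd.where(sd > 0), axis=0)
    z[sd == 0] = 0.0
    z = z.where(df.notna())
    result = z.stack().rename("Z").reset_index()
    result.columns = ["metabolite_id", "organism_id", "Z"]
    result["zero_variance"] = result["metabolite_id"].map((sd == 0).to_dict())
    result["small"] = result["Z"].abs() < 1.0
    return result
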