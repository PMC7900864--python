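"""Proof-of-concept cohort analytics.

Covers the preliminary machine-learning feasibility checks run on the
enrolled cohort:

* descriptive summaries (mean (SD) or median [IQR] per variable, counts and
  integer percentages for binary outcomes),
* a missingness filter retaining variables strictly below a missing-fraction
  threshold (default 25%),
* the per-patient log2 fold-change biomarker matrix versus the cohort median
  (the heat-map input; a display clip of +/-4 is stored alongside the raw
  values, and missing cells stay missing),
* a Kaiser eigenvalue screen: eigendecomposition of the pairwise-complete
  correlation matrix, retaining factors with eigenvalue > 1, with unrotated
  loadings (eigenvectors scaled by sqrt(eigenvalue)),
* an OPTICS reachability diagnostic with a smoothness score that recommends
  hierarchical clustering for jagged profiles (clear density structure) and
  partitioning methods for smooth ones.

The OPTICS pass is implemented exhaustively (O(n^2) distances) with the
canonical semantics: the core distance of a point is the distance to its
min_pts-th nearest neighbour counting the point itself (undefined — +inf —
when that distance exceeds eps); reachability of o from p is
max(core_dist(p), d(p, o)); processing starts at the unprocessed point of
smallest index and always continues with the unprocessed point of smallest
reachability, ties broken by index. The first point of every connected
sweep keeps the +inf sentinel for "undefined".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CohortSummary",
    "LogFoldMatrix",
    "FactorScreenResult",
    "ReachabilityProfile",
    "summarize_cohort",
    "filter_by_missingness",
    "logfold_matrix",
    "kaiser_factor_screen",
    "optics_reachability",
    "smoothness_score",
    "simulate_factor_cohort",
    "clinical_table",
]


# --------------------------------------------------------------------------
# Descriptive summaries
# --------------------------------------------------------------------------


@dataclass
class CohortSummary:
    """Per-variable descriptors: rows keyed by variable name with columns
    depending on kind (mean/sd, median/q1/q3, or count/percent)."""

    table: pd.DataFrame
    n: int


def summarize_cohort(table: pd.DataFrame,
                     variable_config: dict[str, str]) -> CohortSummary:
    """Summarize ``table`` per ``variable_config``: variable name -> one of
    ``"mean_sd"``, ``"median_iqr"`` or ``"binary"``. Descriptors use
    non-missing values only; binary outcomes report count and integer
    percent of non-missing. Unknown variables raise ``KeyError``.
    """
    rows = []
    for var, kind in variable_config.items():
        if var not in table.columns:
            raise KeyError(f"variable {var!r} not present in table")
        col = pd.to_numeric(table[var], errors="coerce").dropna()
        if kind == "mean_sd":
            sd = float(col.std(ddof=1)) if len(col) > 1 else 0.0
            rows.append({"variable": var, "kind": kind, "n": len(col),
                         "mean": float(col.mean()), "sd": sd})
        elif kind == "median_iqr":
            q1, med, q3 = col.quantile([0.25, 0.5, 0.75])
            rows.append({"variable": var, "kind": kind, "n": len(col),
                         "median": float(med), "q1": float(q1), "q3": float(q3)})
        elif kind == "binary":
            count = int(col.sum())
            pct = int(np.floor(100.0 * count / len(col) + 0.5)) if len(col) else 0
            rows.append({"variable": var, "kind": kind, "n": len(col),
                         "count": count, "percent": pct})
        else:
            raise ValueError(f"unknown summary kind {kind!r} for {var!r}")
    out = pd.DataFrame(rows).set_index("variable")
    return CohortSummary(table=out, n=len(table))


def filter_by_missingness(table: pd.DataFrame, threshold: float = 0.25) -> list[str]:
    """Variables whose missing fraction is strictly below ``threshold``.

    A variable missing exactly the threshold fraction is excluded.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    frac = table.isna().mean()
    return [c for c in table.columns if frac[c] < threshold]


# --------------------------------------------------------------------------
# Log-fold biomarker matrix
# --------------------------------------------------------------------------


@dataclass
class LogFoldMatrix:
    """log2(value / column median) per patient and marker. ``values`` holds
    the unclipped entries; ``clipped`` the display matrix bounded at
    +/-``clip``. Missing cells stay NaN (white in the heat map)."""

    values: pd.DataFrame
    clipped: pd.DataFrame
    clip: float
    column_medians: pd.Series


def logfold_matrix(biomarker_table: pd.DataFrame, clip: float = 4.0) -> LogFoldMatrix:
    """Per-patient log2 fold change of each marker versus its cohort median.

    Marker values must be strictly positive; a non-positive cell raises with
    the offending patient and marker named. The median patient of each
    column maps to exactly 0, and column medians of the result are 0.
    """
    num = biomarker_table.apply(pd.to_numeric, errors="coerce")
    bad = (num <= 0).to_numpy() & biomarker_table.notna().to_numpy()
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive biomarker value at patient "
            f"{biomarker_table.index[i]!r}, marker {biomarker_table.columns[j]!r}")
    medians = num.median(axis=0, skipna=True)
    values = np.log2(num.divide(medians, axis=1))
    clipped = values.clip(lower=-clip, upper=clip)
    return LogFoldMatrix(values=values, clipped=clipped, clip=clip,
                         column_medians=medians)


# --------------------------------------------------------------------------
# Kaiser eigenvalue factor screen
# --------------------------------------------------------------------------


@dataclass
class FactorScreenResult:
    eigenvalues: np.ndarray  # descending
    n_retained: int  # eigenvalue > 1, strict
    loadings: pd.DataFrame  # unrotated: eigenvectors * sqrt(eigenvalue)
    correlation: pd.DataFrame


def _is_correlation(df: pd.DataFrame) -> bool:
    if df.shape[0] != df.shape[1]:
        return False
    a = df.to_numpy(dtype=float)
    return (np.allclose(np.diag(a), 1.0, atol=1e-10)
            and np.allclose(a, a.T, atol=1e-10)
            and np.nanmax(np.abs(a)) <= 1.0 + 1e-10)


def kaiser_factor_screen(table_or_correlation: pd.DataFrame) -> FactorScreenResult:
    """Eigenvalue-greater-than-one factor screen.

    Accepts either a raw observation table (correlation computed
    pairwise-complete, so incomplete variables contribute their observed
    pairs rather than being imputed) or a ready correlation matrix
    (square, symmetric, unit diagonal). Constant columns have no defined
    correlation and raise with the offending columns listed.
    """
    df = table_or_correlation
    if df.shape[1] < 2:
        raise ValueError("need at least two variables")
    if _is_correlation(df):
        corr = df.astype(float)
    else:
        num = df.apply(pd.to_numeric, errors="coerce")
        constant = [c for c in num.columns if num[c].dropna().nunique() <= 1]
        if constant:
            raise ValueError(
                f"constant columns have undefined correlation: {constant}")
        corr = num.corr(method="pearson")  # pairwise complete
        if corr.isna().to_numpy().any():
            bad = [c for c in corr.columns if corr[c].isna().any()]
            raise ValueError(f"correlation undefined for columns: {bad}")
    evals, evecs = np.linalg.eigh(corr.to_numpy(dtype=float))
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_retained = int((evals > 1.0).sum())
    loadings = pd.DataFrame(
        evecs * np.sqrt(np.clip(evals, 0.0, None)),
        index=corr.index,
        columns=[f"factor_{i + 1}" for i in range(len(evals))])
    return FactorScreenResult(eigenvalues=evals, n_retained=n_retained,
                              loadings=loadings, correlation=corr)


def simulate_factor_cohort(n_obs: int, n_vars: int, n_factors: int,
                           loading: float = 0.7, seed: int = 0) -> pd.DataFrame:
    """Observations from an orthogonal block latent factor model.

    Variables are split into ``n_factors`` contiguous, as-equal-as-possible
    blocks; each variable loads ``loading`` on its block's factor with unique
    variance ``1 - loading**2`` (0.51 at the default 0.7), giving unit-
    variance observed variables. Used to verify that the eigenvalue screen
    recovers the generating factor count.
    """
    if not 0.0 < loading < 1.0:
        raise ValueError("loading must be in (0, 1)")
    if n_factors < 1 or n_factors > n_vars:
        raise ValueError("need 1 <= n_factors <= n_vars")
    rng = np.random.default_rng(seed)
    factors = rng.normal(size=(n_obs, n_factors))
    block = np.array_split(np.arange(n_vars), n_factors)
    lam = np.zeros((n_vars, n_factors))
    for k, idx in enumerate(block):
        lam[idx, k] = loading
    unique_sd = np.sqrt(1.0 - loading ** 2)
    x = factors @ lam.T + rng.normal(scale=unique_sd, size=(n_obs, n_vars))
    return pd.DataFrame(x, columns=[f"v{i + 1}" for i in range(n_vars)])


# --------------------------------------------------------------------------
# OPTICS reachability diagnostic
# --------------------------------------------------------------------------


@dataclass
class ReachabilityProfile:
    """OPTICS output: the visit order (a permutation of input indices), the
    reachability distance at each position (+inf = undefined, always at the
    first position of a sweep), per-point core distances, and parameters."""

    order: np.ndarray
    reachability: np.ndarray  # aligned with order
    core_distances: np.ndarray  # aligned with input index
    min_pts: int
    eps: float


def optics_reachability(points, min_pts: int = 5,
                        eps: float = np.inf) -> ReachabilityProfile:
    """Exhaustive OPTICS ordering with reachability distances.

    ``points`` is an (n, d) array of coordinates under the Euclidean metric
    (standardize beforehand when variables live on different scales). The
    core distance of a point is the distance to its ``min_pts``-th nearest
    neighbour counting itself, undefined (inf) if that exceeds ``eps``;
    reachability(o <- p) = max(core_dist(p), d(p, o)); ties in the
    min-priority scan break toward the smallest index.
    """
    x = np.asarray(points, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = len(x)
    if min_pts < 2:
        raise ValueError("min_pts must be >= 2")
    if n < min_pts:
        raise ValueError(f"need at least min_pts={min_pts} points, got {n}")

    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    kth = np.sort(d, axis=1)[:, min_pts - 1]  # includes self at distance 0
    core = np.where(kth <= eps, kth, np.inf)

    reach = np.full(n, np.inf)
    processed = np.zeros(n, dtype=bool)
    order = np.empty(n, dtype=int)
    reach_at_visit = np.empty(n, dtype=float)

    for pos in range(n):
        candidates = np.flatnonzero(~processed)
        p = candidates[np.argmin(reach[candidates])]  # argmin: first = lowest index
        processed[p] = True
        order[pos] = p
        reach_at_visit[pos] = reach[p]
        if np.isfinite(core[p]):
            neighbours = np.flatnonzero(~processed & (d[p] <= eps))
            newreach = np.maximum(core[p], d[p, neighbours])
            reach[neighbours] = np.minimum(reach[neighbours], newreach)

    return ReachabilityProfile(order=order, reachability=reach_at_visit,
                               core_distances=core, min_pts=min_pts, eps=eps)


def smoothness_score(profile: ReachabilityProfile,
                     threshold: float = 0.5) -> tuple[float, str]:
    """Jaggedness score of a reachability profile and a clustering-family
    recommendation.

    The score is the mean absolute successive difference of the finite
    reachability values (in visit order) normalized by their interquartile
    range. A constant profile scores 0. Scores at or above ``threshold``
    read as jagged (clear density structure -> hierarchical clustering);
    below as smooth (-> partitioning methods). The threshold is an explicit
    heuristic default, configurable by the caller.
    """
    finite = profile.reachability[np.isfinite(profile.reachability)]
    if len(finite) < 3:
        raise ValueError("need at least 3 finite reachability values")
    diffs = np.abs(np.diff(finite))
    mad = float(diffs.mean())
    q1, q3 = np.percentile(finite, [25, 75])
    iqr = float(q3 - q1)
    if mad == 0.0:
        score = 0.0
    elif iqr == 0.0:
        score = np.inf
    else:
        score = mad / iqr
    recommendation = "hierarchical" if score >= threshold else "partitioning"
    return score, recommendation


# --------------------------------------------------------------------------
# Clinical wide table (events -> per-encounter variables)
# --------------------------------------------------------------------------


def clinical_table(events: pd.DataFrame, encounter_ids=None,
                   window_minutes: int = 360,
                   codes: list[str] | None = None) -> pd.DataFrame:
    """Wide per-encounter table of first-in-window values for numeric codes.

    The factor screen and OPTICS diagnostic run on this table after the
    missingness filter and z-scoring. ``codes`` defaults to every vital/lab
    code present in the stream.
    """
    ev = events[(events["t_minutes"] >= 0) & (events["t_minutes"] < window_minutes)
                & events["kind"].isin(["vital", "lab"])]
    if codes is not None:
        ev = ev[ev["code"].isin(codes)]
    ev = ev.copy()
    ev["value"] = pd.to_numeric(ev["value"], errors="coerce")
    first = (ev.sort_values("t_minutes", kind="mergesort")
             .groupby(["encounter_id", "code"])["value"].first())
    wide = first.unstack()
    if encounter_ids is not None:
        wide = wide.reindex(pd.Index(encounter_ids, name="encounter_id"))
    return wide
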