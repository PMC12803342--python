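"""Poisson maximum-likelihood estimation of per-sequence binding affinity.

Model
-----
Under non-cooperative single-site equilibrium binding, a sequence with
association constant K (nM^-1) at free-protein concentration C (nM) is
occupied with probability

    P = K*C / (1 + K*C).

A per-sequence well-retention parameter w in [0, 1] is the probability that
a DNA molecule never reaches the bound band (stuck in the gel well, uneven
migration), scaling the *bound* expectation by (1 - w); the unbound
expectation is left unscaled.

Expected read counts follow from the library composition and per-sample
sequencing depths:

    lambda_B(i,j,r) = N_B(j,r) * f_i(r) / D_j  * (1 - w_i) * P(K_i, C_j)
    lambda_U(i,j,r) = N_U(j,r) * f_i(r) / D_uj * (1 - P(K_i, C_j))
    lambda_L(i,r)   = N_L(r)   * f_i(r)

where f_i(r) is the sequence's fraction of the input library and D_j, D_uj
are per-concentration normalizers shared across replicates.  Counts are
Poisson; dropping the data-only log(n!) terms, the objective minimized is
sum(lambda - n*log(lambda)) over bound and unbound cells at all retained
positive concentrations plus the library cells.

Fitting alternates per-sequence likelihood maximization (L-BFGS-B on log10 K,
then on (log10 K, w)) with denominator refreshes D_j = sum_i f_i*(1-w_i)*P_ij
and D_uj = sum_i f_i*(1-P_ij), which make expected fractions self-consistent
with the fitted binding landscape.  Phase 1 (w fixed at 0) iterates until the
denominators plateau; phase 2 releases w for a fixed number of refinement
rounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .read_processing import ReadCountTable, SampleKey

__all__ = [
    "ConcentrationSeries",
    "Denominators",
    "FitConfig",
    "FitData",
    "ExpectedCounts",
    "DEFAULT_CONCENTRATIONS",
    "occupancy",
    "occupancy_with_well",
    "expected_counts",
    "neg_log_likelihood",
    "initialize_denominators",
    "exclude_low_coverage_concentrations",
    "build_fit_data",
    "fit",
]

#: the assay's concentration series in nM
DEFAULT_CONCENTRATIONS = (0.0, 100.0, 500.0, 1000.0, 1500.0, 2000.0, 3000.0)

LN10 = np.log(10.0)
_LAMBDA_FLOOR = 1e-12
#: finite sentinel standing in for an infinite Poisson penalty
NLL_SENTINEL = 1e30


@dataclass(frozen=True)
class ConcentrationSeries:
    """Ordered protein concentrations, with an exclusion set and reasons."""

    values: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    excluded: dict[float, str] = field(default_factory=dict)

    def __post_init__(self):
        vals = tuple(float(v) for v in self.values)
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("concentrations must be strictly increasing")
        if not set(self.excluded) <= set(vals):
            raise ValueError("excluded concentrations must be a subset of values")
        object.__setattr__(self, "values", vals)

    @property
    def active(self) -> tuple[float, ...]:
        return tuple(v for v in self.values if v not in self.excluded)

    def exclude(self, conc: float, reason: str) -> "ConcentrationSeries":
        return replace(self, excluded={**self.excluded, float(conc): reason})


@dataclass
class Denominators:
    """Per-concentration normalizers D_j (bound) and D_uj (unbound).

    Shared across replicates; the full trajectory is kept so convergence
    plateaus can be inspected.
    """

    bound: dict[float, float]
    unbound: dict[float, float]
    history: list[tuple[dict[float, float], dict[float, float]]] = field(default_factory=list)

    def snapshot(self) -> None:
        self.history.append((dict(self.bound), dict(self.unbound)))

    def to_frame(self, tf: str = "") -> pd.DataFrame:
        rows = []
        for it, (b, u) in enumerate(self.history + [(self.bound, self.unbound)]):
            for c in sorted(b):
                rows.append(
                    {"tf": tf, "concentration_nM": c, "D_bound": b[c],
                     "D_unbound": u[c], "iteration": it}
                )
        return pd.DataFrame(rows)


@dataclass
class FitConfig:
    """Optimizer and model knobs.

    log10 K is bounded in [-7, 1] (K in nM^-1); w in [0, 1].  0 nM samples
    are excluded from the likelihood by default: the model predicts zero
    bound signal there, so they carry no information about K and serve QC
    instead.
    """

    phase1_max_iter: int = 1000
    phase2_iter: int = 10
    denom_tol: float = 1e-4
    log10K_bounds: tuple[float, float] = (-7.0, 1.0)
    log10K_init: float = -3.0
    include_zero_nM: bool = False
    refresh_denominators_phase2: bool = True
    update_unbound_denominators: bool = True
    min_bound_total: float = 1e4


# ---------------------------------------------------------------------------
# Occupancy model
# ---------------------------------------------------------------------------

def occupancy(K, C):
    """Equilibrium binding probability K*C / (1 + K*C)."""
    K = np.asarray(K, dtype=float)
    C = np.asarray(C, dtype=float)
    kc = K * C
    return kc / (1.0 + kc)


def occupancy_with_well(K, C, w):
    """Bound-band probability (1 - w) * K*C / (1 + K*C)."""
    return (1.0 - np.asarray(w, dtype=float)) * occupancy(K, C)


# ---------------------------------------------------------------------------
# Data container: counts pivoted to arrays
# ---------------------------------------------------------------------------

@dataclass
class FitData:
    """Counts for one TF pivoted to arrays over (sequence, concentration, replicate)."""

    sequences: list[tuple[str, str]]
    concentrations: np.ndarray     # (J,) positive concentrations in the likelihood
    replicates: list[str]
    n_bound: np.ndarray            # (S, J, R)
    n_unbound: np.ndarray          # (S, J, R)
    n_library: np.ndarray          # (S, R)
    N_bound: np.ndarray            # (J, R)
    N_unbound: np.ndarray          # (J, R)
    N_library: np.ndarray          # (R,)
    library_fraction: np.ndarray   # (S, R) = n_library / N_library


def build_fit_data(
    table: ReadCountTable,
    series: ConcentrationSeries,
    sequences: Sequence[tuple[str, str]],
    tf: Optional[str] = None,
    include_zero_nM: bool = False,
) -> FitData:
    """Pivot a count table to the arrays the likelihood consumes.

    Sample totals N are over *all* assigned reads in each sample (the
    library fractions f_i then sum to <= 1 over the retained sequences).
    """
    if tf is None:
        tfs = sorted({k.tf for k in table.samples})
        if len(tfs) != 1:
            raise ValueError(f"table holds {len(tfs)} TFs; pass tf= explicitly")
        tf = tfs[0]
    concs = [c for c in series.active if include_zero_nM or c > 0]
    reps = sorted({k.replicate for k in table.samples if k.tf == tf and k.fraction != "library"})
    if not concs or not reps:
        raise ValueError("no active concentrations or replicates to fit")
    totals = table.totals
    lib_keys = [k for k in table.samples if k.tf == tf and k.fraction == "library"]
    if not lib_keys:
        raise ValueError(f"missing library sample for tf {tf!r}")
    lib_by_rep = {}
    for r in reps:
        matches = [k for k in lib_keys if k.replicate == r]
        lib_by_rep[r] = matches[0] if matches else lib_keys[0]

    S, J, R = len(sequences), len(concs), len(reps)
    nB = np.zeros((S, J, R))
    nU = np.zeros((S, J, R))
    nL = np.zeros((S, R))
    NB = np.zeros((J, R))
    NU = np.zeros((J, R))
    NL = np.zeros(R)
    seq_idx = {s: i for i, s in enumerate(sequences)}
    for j, c in enumerate(concs):
        for r, rep in enumerate(reps):
            bk = SampleKey(tf, "bound", c, rep)
            uk = SampleKey(tf, "unbound", c, rep)
            for frac, key, N_arr, n_arr in (("bound", bk, NB, nB), ("unbound", uk, NU, nU)):
                if key not in totals:
                    raise ValueError(f"missing sample: {key}")
                N_arr[j, r] = totals[key]
    for r, rep in enumerate(reps):
        NL[r] = totals[lib_by_rep[rep]]
    for (rsid, allele, k), n in table.counts.items():
        if k.tf != tf:
            continue
        i = seq_idx.get((rsid, allele))
        if i is None:
            continue
        if k.fraction == "library":
            for r, rep in enumerate(reps):
                if lib_by_rep[rep] == k:
                    nL[i, r] = n
        elif k.conc_value in concs:
            j = concs.index(k.conc_value)
            r = reps.index(k.replicate)
            if k.fraction == "bound":
                nB[i, j, r] = n
            else:
                nU[i, j, r] = n
    if np.any(NL <= 0):
        raise ValueError("library sample has zero assigned reads")
    f = nL / NL[None, :]
    return FitData(
        sequences=list(sequences),
        concentrations=np.asarray(concs, dtype=float),
        replicates=reps,
        n_bound=nB, n_unbound=nU, n_library=nL,
        N_bound=NB, N_unbound=NU, N_library=NL,
        library_fraction=f,
    )


# ---------------------------------------------------------------------------
# Expected counts and likelihood
# ---------------------------------------------------------------------------

@dataclass
class ExpectedCounts:
    """Poisson means per cell: bound/unbound (S,J,R) and library (S,R)."""

    lambda_bound: np.ndarray
    lambda_unbound: np.ndarray
    lambda_library: np.ndarray


def _denominator_arrays(denominators: Denominators, concs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    try:
        D = np.array([denominators.bound[c] for c in concs])
        Du = np.array([denominators.unbound[c] for c in concs])
    except KeyError as e:
        raise ValueError(f"no denominator for concentration {e.args[0]}") from e
    if np.any(D <= 0) or np.any(Du <= 0):
        raise ValueError("denominators must be positive")
    return D, Du


def expected_counts(
    K: np.ndarray,
    w: np.ndarray,
    data: FitData,
    denominators: Denominators,
) -> ExpectedCounts:
    """Model-expected counts for every observed cell.

    The library expectation N_L * f_i is concentration-independent and does
    not depend on (K, w); it enters the likelihood as a data-consistency
    term only.
    """
    K = np.atleast_1d(np.asarray(K, dtype=float))
    w = np.atleast_1d(np.asarray(w, dtype=float))
    D, Du = _denominator_arrays(denominators, data.concentrations)
    P = occupancy(K[:, None], data.concentrations[None, :])          # (S, J)
    Pw = (1.0 - w[:, None]) * P
    f = data.library_fraction                                        # (S, R)
    lamB = data.N_bound[None, :, :] * f[:, None, :] / D[None, :, None] * Pw[:, :, None]
    lamU = data.N_unbound[None, :, :] * f[:, None, :] / Du[None, :, None] * (1.0 - P)[:, :, None]
    lamL = data.N_library[None, :] * f
    return ExpectedCounts(lamB, lamU, lamL)


def _poisson_nll_terms(n: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Per-cell lambda - n*log(lambda), with 0*log(0) := 0 and an infinite
    penalty (large finite sentinel) where lambda == 0 but n > 0."""
    lam = np.asarray(lam, dtype=float)
    n = np.asarray(n, dtype=float)
    out = lam - n * np.log(np.clip(lam, _LAMBDA_FLOOR, None))
    bad = (lam <= 0) & (n > 0)
    if np.any(bad):
        out = np.where(bad, NLL_SENTINEL, out)
    out = np.where((lam <= 0) & (n <= 0), 0.0, out)
    return out


def neg_log_likelihood(data: FitData, expected: ExpectedCounts) -> float:
    """Negative joint log-likelihood, log(n!) terms omitted.

    Sums bound and unbound cells over both replicates and all retained
    concentrations, plus the library cells.
    """
    return float(
        _poisson_nll_terms(data.n_bound, expected.lambda_bound).sum()
        + _poisson_nll_terms(data.n_unbound, expected.lambda_unbound).sum()
        + _poisson_nll_terms(data.n_library, expected.lambda_library).sum()
    )


def _per_sequence_nll(data: FitData, expected: ExpectedCounts) -> np.ndarray:
    return (
        _poisson_nll_terms(data.n_bound, expected.lambda_bound).sum(axis=(1, 2))
        + _poisson_nll_terms(data.n_unbound, expected.lambda_unbound).sum(axis=(1, 2))
        + _poisson_nll_terms(data.n_library, expected.lambda_library).sum(axis=1)
    )


# ---------------------------------------------------------------------------
# Denominator initialization and updates
# ---------------------------------------------------------------------------

def initialize_denominators(
    enrich: pd.DataFrame,
    series: ConcentrationSeries,
    sequences: Optional[Sequence[tuple[str, str]]] = None,
) -> tuple[Denominators, ConcentrationSeries]:
    """D_j = 0.9 / max retained enrichment at concentration j; D_uj = 1.

    Enrichment is replicate-averaged per sequence before taking the max.
    Concentrations with no retained sequence are auto-excluded.
    """
    sub = enrich
    if sequences is not None:
        keep = set(sequences)
        sub = enrich[[tuple(x) in keep for x in zip(enrich["rsid"], enrich["allele"])]]
    bound_d: dict[float, float] = {}
    unbound_d: dict[float, float] = {}
    for c in series.active:
        at_c = sub[sub["concentration_nM"] == c]
        if at_c.empty:
            warnings.warn(f"no retained sequences at {c} nM; concentration excluded")
            series = series.exclude(c, "no retained sequences")
            continue
        per_seq = at_c.groupby(["rsid", "allele"])["enrichment"].mean()
        bound_d[c] = 0.9 / float(per_seq.max())
        unbound_d[c] = 1.0
    return Denominators(bound=bound_d, unbound=unbound_d), series


def _update_denominators(
    den: Denominators,
    data: FitData,
    K: np.ndarray,
    w: np.ndarray,
    update_unbound: bool = True,
) -> float:
    """Refresh D_j, D_uj from the current parameters; return the max relative change."""
    f_mean = data.library_fraction.mean(axis=1)                      # (S,)
    P = occupancy(K[:, None], data.concentrations[None, :])          # (S, J)
    Pw = (1.0 - w[:, None]) * P
    new_b = (f_mean[:, None] * Pw).sum(axis=0)
    new_u = (f_mean[:, None] * (1.0 - P)).sum(axis=0)
    den.snapshot()
    delta = 0.0
    for j, c in enumerate(data.concentrations):
        nb = max(float(new_b[j]), _LAMBDA_FLOOR)
        delta = max(delta, abs(nb - den.bound[c]) / den.bound[c])
        den.bound[c] = nb
        if update_unbound:
            nu = max(float(new_u[j]), _LAMBDA_FLOOR)
            delta = max(delta, abs(nu - den.unbound[c]) / den.unbound[c])
            den.unbound[c] = nu
    return delta


def exclude_low_coverage_concentrations(
    table: ReadCountTable,
    series: ConcentrationSeries,
    min_bound_total: float = 1e4,
    manual: Sequence[float] = (),
    tf: Optional[str] = None,
) -> ConcentrationSeries:
    """Exclude concentrations whose bound fraction is too shallow to fit.

    A concentration is dropped when its total bound count, summed over
    replicates, is below ``min_bound_total``; user-supplied ``manual``
    exclusions are honored in addition.
    """
    totals = table.totals
    for c in series.values:
        if c in series.excluded or c == 0:
            continue
        tot = sum(
            n for k, n in totals.items()
            if k.fraction == "bound" and k.conc_value == c and (tf is None or k.tf == tf)
        )
        if tot < min_bound_total:
            series = series.exclude(c, "insufficient bound counts")
    for c in manual:
        if float(c) not in series.excluded:
            series = series.exclude(float(c), "manual exclusion")
    return series


# ---------------------------------------------------------------------------
# Per-sequence objective and the two-phase fit
# ---------------------------------------------------------------------------

def _seq_objective(params, fit_w, i, data, D, Du, nB, nU):
    """NLL and gradient for one sequence at frozen denominators.

    Parameters are (log10 K,) in phase 1 or (log10 K, w) in phase 2.
    """
    logK = params[0]
    w = params[1] if fit_w else 0.0
    K = 10.0 ** logK
    C = data.concentrations
    theta = K * C / (1.0 + K * C)                                    # (J,)
    f = data.library_fraction[i]                                     # (R,)
    A = data.N_bound * f[None, :] / D[:, None] * theta[:, None]      # (J, R)
    lamB = (1.0 - w) * A
    lamU = data.N_unbound * f[None, :] / Du[:, None] * (1.0 - theta)[:, None]
    lamB_s = np.clip(lamB, _LAMBDA_FLOOR, None)
    lamU_s = np.clip(lamU, _LAMBDA_FLOOR, None)
    nll = float(np.sum(lamB - nB * np.log(lamB_s)) + np.sum(lamU - nU * np.log(lamU_s)))
    # gradients
    resB = 1.0 - nB / lamB_s
    resU = 1.0 - nU / lamU_s
    dtheta = (theta * (1.0 - theta))[:, None] * LN10                 # d theta / d log10K
    dlamB = (1.0 - w) * data.N_bound * f[None, :] / D[:, None] * dtheta
    dlamU = -data.N_unbound * f[None, :] / Du[:, None] * dtheta
    g_logK = float(np.sum(resB * dlamB) + np.sum(resU * dlamU))
    if fit_w:
        g_w = float(np.sum(resB * (-A)))
        return nll, np.array([g_logK, g_w])
    return nll, np.array([g_logK])


def _optimize_round(data, den, logK, w, fit_w, cfg, failed):
    D, Du = _denominator_arrays(den, data.concentrations)
    (lo, hi) = cfg.log10K_bounds
    for i in range(len(data.sequences)):
        if failed[i]:
            continue
        if fit_w:
            x0 = np.array([logK[i], w[i]])
            bounds = [(lo, hi), (0.0, 1.0)]
        else:
            x0 = np.array([logK[i]])
            bounds = [(lo, hi)]
        res = minimize(
            _seq_objective, x0,
            args=(fit_w, i, data, D, Du, data.n_bound[i], data.n_unbound[i]),
            method="L-BFGS-B", jac=True, bounds=bounds,
        )
        if not res.success and not np.isfinite(res.fun):
            failed[i] = True
            continue
        logK[i] = res.x[0]
        if fit_w:
            w[i] = res.x[1]


def fit(
    table: ReadCountTable,
    flags: pd.DataFrame,
    series: ConcentrationSeries,
    config: FitConfig | None = None,
    enrich: Optional[pd.DataFrame] = None,
    tf: Optional[str] = None,
) -> tuple[pd.DataFrame, Denominators]:
    """Two-phase maximum-likelihood fit of (K, w) for every QC-passing sequence.

    Phase 1 alternates per-sequence optimization of log10 K (w = 0) with
    denominator refreshes until the denominators change by less than
    ``denom_tol`` (relative) or ``phase1_max_iter`` rounds.  Phase 2 then
    alternates per-sequence (log10 K, w) optimization with denominator
    refreshes for exactly ``phase2_iter`` rounds.

    Returns (fits, denominators); fits has one row per sequence with columns
    rsid, allele, K_nM_inv, w, neg_log_likelihood, converged, n_iterations.
    Sequences whose optimizer fails get NaN parameters and converged=False;
    the run continues unless every sequence fails.
    """
    from .enrichment_qc import enrichment_table

    cfg = config or FitConfig()
    retained = [tuple(ix) for ix, ok in flags["overall_pass"].items() if ok]
    if not retained:
        raise ValueError("no sequences passed QC; nothing to fit")
    if enrich is None:
        enrich = enrichment_table(table, sequences=retained)
    den, series = initialize_denominators(enrich, series, retained)
    data = build_fit_data(table, series, retained, tf=tf, include_zero_nM=cfg.include_zero_nM)

    S = len(data.sequences)
    logK = np.full(S, cfg.log10K_init)
    w = np.zeros(S)
    failed = np.zeros(S, dtype=bool)
    # sequences absent from the library cannot be fit (lambda identically 0)
    failed |= data.library_fraction.sum(axis=1) <= 0

    n_iter = 0
    for _ in range(cfg.phase1_max_iter):
        _optimize_round(data, den, logK, w, False, cfg, failed)
        n_iter += 1
        delta = _update_denominators(den, data, 10.0 ** logK, w, cfg.update_unbound_denominators)
        if delta < cfg.denom_tol:
            break
    for _ in range(cfg.phase2_iter):
        _optimize_round(data, den, logK, w, True, cfg, failed)
        n_iter += 1
        if cfg.refresh_denominators_phase2:
            _update_denominators(den, data, 10.0 ** logK, w, cfg.update_unbound_denominators)

    if failed.all():
        raise RuntimeError("optimizer failed for every sequence")

    K = 10.0 ** logK
    exp = expected_counts(K, w, data, den)
    nll = _per_sequence_nll(data, exp)
    rows = []
    for i, (rsid, allele) in enumerate(data.sequences):
        ok = not failed[i]
        rows.append(
            {
                "rsid": rsid,
                "allele": allele,
                "K_nM_inv": K[i] if ok else np.nan,
                "w": w[i] if ok else np.nan,
                "neg_log_likelihood": nll[i] if ok else np.nan,
                "converged": bool(ok),
                "n_iterations": n_iter,
            }
        )
    fits = pd.DataFrame(rows)
    if tf is not None:
        fits.insert(2, "tf", tf)
    return fits, den
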