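"""Bound/unbound enrichment with pseudo-counts, and sequence-level QC filters.

Enrichment compares a sequence's relative frequency in the bound band to the
unbound band at the same concentration.  Pseudo-counts — 2.5 reads per
million scaled by each sample's total — keep the ratio finite and damp
shot noise at low counts.  Five filters on the 0 nM and input-library
samples remove sequences whose baseline behaviour (gel irregularities,
depletion, poor representation) would corrupt downstream affinity fits;
protein-positive samples never influence the filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .read_processing import ReadCountTable, SampleKey

__all__ = [
    "FilterConfig",
    "pseudo_count",
    "enrichment",
    "enrichment_table",
    "apply_filters",
    "replicate_concordance",
]

#: pseudo-count rate: reads per million of sample total
PSEUDO_PER_MILLION = 2.5

#: ppm floor for the low-count filters
MIN_PPM = 5.0


def pseudo_count(total_reads: float) -> float:
    """Pseudo-count for a sample: 2.5 reads per million, scaled by its total."""
    if total_reads < 0:
        raise ValueError("total_reads must be non-negative")
    return PSEUDO_PER_MILLION * total_reads / 1e6


def enrichment(n_bound: float, N_bound: float, n_unbound: float, N_unbound: float) -> float:
    """Pseudo-count-adjusted bound/unbound enrichment for one sequence.

    ((n_b + p_b)/N_b) / ((n_u + p_u)/N_u) with p = pseudo_count(N) per
    fraction.  Finite and positive whenever both totals are positive.
    """
    if N_bound <= 0 or N_unbound <= 0:
        raise ValueError("enrichment undefined for non-positive sample totals")
    f_b = (n_bound + pseudo_count(N_bound)) / N_bound
    f_u = (n_unbound + pseudo_count(N_unbound)) / N_unbound
    return f_b / f_u


@dataclass
class FilterConfig:
    """Knobs for the five QC filters and the recovery check.

    ``*_replicate_mode`` is "either" (fail if violated in either replicate)
    or "both" (fail only when violated in both).  Ratio filters use raw ppm
    without pseudo-counts; a zero denominator fails the filter.
    """

    unbound_library_ratio_low: float = 0.2
    unbound_library_ratio_high: float = 2.0
    bound_unbound_ratio_low: float = 0.2
    bound_unbound_ratio_high: float = 5.0
    min_ppm: float = MIN_PPM
    filter1_replicate_mode: str = "either"
    filter2_replicate_mode: str = "both"
    filter3_replicate_mode: str = "either"
    filter4_replicate_mode: str = "either"
    filter5_replicate_mode: str = "both"
    recovery_r_min: float = 0.5


FILTER_COLUMNS = [
    "filter1_unbound0_library_ratio",
    "filter2_low_unbound0",
    "filter3_low_library",
    "filter4_bound0_unbound0_ratio",
    "filter5_base_representation",
]


def _sample_ppm(table: ReadCountTable, key: SampleKey) -> tuple[dict, int]:
    total = table.total(key)
    ppm = {
        (rsid, allele): n / total * 1e6
        for (rsid, allele, k), n in table.counts.items()
        if k == key
    } if total > 0 else {}
    return ppm, total


def _zero_keys(table: ReadCountTable, tf: str):
    reps = sorted({k.replicate for k in table.samples if k.tf == tf})
    if not reps:
        raise ValueError(f"no samples for tf {tf!r}")
    keys = {}
    for frac in ("bound", "unbound"):
        for rep in reps:
            key = SampleKey(tf, frac, 0.0, rep)
            if key not in table.samples:
                raise ValueError(f"missing required 0 nM sample: {key}")
            keys[(frac, rep)] = key
    lib_keys = [k for k in table.samples if k.tf == tf and k.fraction == "library"]
    if not lib_keys:
        raise ValueError(f"missing library sample for tf {tf!r}")
    # one library sequencing per replicate; a single file is shared by both
    lib_by_rep = {}
    for rep in reps:
        matches = [k for k in lib_keys if k.replicate == rep]
        lib_by_rep[rep] = matches[0] if matches else lib_keys[0]
    return reps, keys, lib_by_rep


def enrichment_table(
    table: ReadCountTable,
    sequences: Optional[Sequence[tuple[str, str]]] = None,
) -> pd.DataFrame:
    """Per-(sequence, tf, concentration, replicate) enrichment values.

    ``sequences`` defaults to every (rsid, allele) observed in the table.
    Rows are emitted for every bound/unbound pair sharing (tf, concentration,
    replicate); pairs whose samples have zero totals are skipped.
    """
    if sequences is None:
        sequences = sorted({(r, a) for (r, a, _) in table.counts})
    totals = table.totals
    rows = []
    bound_keys = [k for k in table.samples if k.fraction == "bound"]
    for bk in bound_keys:
        uk = SampleKey(bk.tf, "unbound", bk.concentration_nM, bk.replicate)
        if uk not in totals:
            continue
        N_b, N_u = totals[bk], totals[uk]
        if N_b <= 0 or N_u <= 0:
            continue
        p_b, p_u = pseudo_count(N_b), pseudo_count(N_u)
        for rsid, allele in sequences:
            n_b = table.counts.get((rsid, allele, bk), 0)
            n_u = table.counts.get((rsid, allele, uk), 0)
            rows.append(
                {
                    "rsid": rsid,
                    "allele": allele,
                    "tf": bk.tf,
                    "concentration_nM": bk.concentration_nM,
                    "replicate": bk.replicate,
                    "enrichment": ((n_b + p_b) / N_b) / ((n_u + p_u) / N_u),
                }
            )
    return pd.DataFrame(
        rows, columns=["rsid", "allele", "tf", "concentration_nM", "replicate", "enrichment"]
    )


def _ratio_fail(num: float, den: float, low: float, high: float) -> bool:
    if den <= 0:
        return True
    r = num / den
    return r <= low or r >= high


def _combine(fails: list[bool], mode: str) -> bool:
    return all(fails) if mode == "both" else any(fails)


def apply_filters(
    table: ReadCountTable,
    tf: Optional[str] = None,
    config: FilterConfig | None = None,
) -> pd.DataFrame:
    """Evaluate the five QC filters plus the recovery flag per sequence.

    Returns a DataFrame indexed by (rsid, allele) with one boolean column
    per filter (True = pass), a ``recovery_flag`` (True = suspicious loss,
    informational only), and ``overall_pass`` (AND of filters 1-5).

    Only the 0 nM bound/unbound samples and the library sample(s) are read;
    protein-positive concentrations cannot change the outcome.
    """
    cfg = config or FilterConfig()
    if tf is None:
        tfs = sorted({k.tf for k in table.samples})
        if len(tfs) != 1:
            raise ValueError(f"table holds {len(tfs)} TFs; pass tf= explicitly")
        tf = tfs[0]
    reps, keys, lib_by_rep = _zero_keys(table, tf)

    ppm_u0 = {r: _sample_ppm(table, keys[("unbound", r)])[0] for r in reps}
    ppm_b0 = {r: _sample_ppm(table, keys[("bound", r)])[0] for r in reps}
    ppm_lib = {r: _sample_ppm(table, lib_by_rep[r])[0] for r in reps}
    totals = table.totals

    sequences = sorted(
        {(rs, a) for (rs, a, k) in table.counts if k.tf == tf}
    )
    by_rsid: dict[str, list[tuple[str, str]]] = {}
    for s in sequences:
        by_rsid.setdefault(s[0], []).append(s)

    g = cfg.min_ppm
    records = []
    for rsid, allele in sequences:
        s = (rsid, allele)
        f1 = not _combine(
            [
                _ratio_fail(
                    ppm_u0[r].get(s, 0.0), ppm_lib[r].get(s, 0.0),
                    cfg.unbound_library_ratio_low, cfg.unbound_library_ratio_high,
                )
                for r in reps
            ],
            cfg.filter1_replicate_mode,
        )
        f2 = not _combine(
            [ppm_u0[r].get(s, 0.0) < g for r in reps], cfg.filter2_replicate_mode
        )
        f3 = not _combine(
            [ppm_lib[r].get(s, 0.0) < g for r in reps], cfg.filter3_replicate_mode
        )
        f4 = not _combine(
            [
                _ratio_fail(
                    ppm_b0[r].get(s, 0.0), ppm_u0[r].get(s, 0.0),
                    cfg.bound_unbound_ratio_low, cfg.bound_unbound_ratio_high,
                )
                for r in reps
            ],
            cfg.filter4_replicate_mode,
        )
        # filter 5: every allele sequence of the variant must be represented
        # in the library
        f5 = not _combine(
            [
                any(ppm_lib[r].get(sib, 0.0) < g for sib in by_rsid[rsid])
                for r in reps
            ],
            cfg.filter5_replicate_mode,
        )
        # recovery check (Eq. 4-5 spirit): at 0 nM the bound+unbound
        # fractions should recover roughly the library fraction
        rec_fail = []
        for r in reps:
            lib_frac = ppm_lib[r].get(s, 0.0) / 1e6
            got = (ppm_b0[r].get(s, 0.0) + ppm_u0[r].get(s, 0.0)) / 1e6
            rec_fail.append(lib_frac > 0 and got < cfg.recovery_r_min * lib_frac)
        recovery_flag = all(rec_fail)

        records.append(
            {
                "rsid": rsid,
                "allele": allele,
                FILTER_COLUMNS[0]: f1,
                FILTER_COLUMNS[1]: f2,
                FILTER_COLUMNS[2]: f3,
                FILTER_COLUMNS[3]: f4,
                FILTER_COLUMNS[4]: f5,
                "recovery_flag": recovery_flag,
                "overall_pass": f1 and f2 and f3 and f4 and f5,
            }
        )
    return pd.DataFrame(records).set_index(["rsid", "allele"])


def replicate_concordance(enrich: pd.DataFrame) -> pd.Series:
    """Per-TF R^2 of replicate-2 vs replicate-1 enrichment, excluding 0 nM.

    Fitted by ordinary least squares (so a constant scale factor between
    replicates still yields R^2 = 1).  TFs with a single replicate are
    omitted with a warning.
    """
    import warnings

    out = {}
    for tf, sub in enrich.groupby("tf"):
        sub = sub[sub["concentration_nM"] > 0]
        reps = sorted(sub["replicate"].unique())
        if len(reps) < 2:
            warnings.warn(f"{tf}: single replicate, concordance not computed")
            continue
        wide = sub.pivot_table(
            index=["rsid", "allele", "concentration_nM"],
            columns="replicate",
            values="enrichment",
        ).dropna()
        x, y = wide[reps[0]].to_numpy(), wide[reps[1]].to_numpy()
        if len(x) < 2 or np.allclose(x, x[0]):
            warnings.warn(f"{tf}: degenerate enrichment values, concordance not computed")
            continue
        out[tf] = stats.linregress(x, y).rvalue ** 2
    return pd.Series(out, name="r_squared", dtype=float)
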