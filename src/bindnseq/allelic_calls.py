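"""Allele-biased binding calls from fitted affinities.

A variant shows allelic binding for a TF when an alternate allele's fitted
K differs from the reference allele's by at least a fold threshold (2 by
default).  Fold change is alt/ref, so "increase" means the alternate allele
binds more tightly.  The call is a pure fold-change rule — no significance
test is attached.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .library_model import VariantRecord, allele_labels

__all__ = ["call_allelic", "intersect_tfs", "top_n_by_affinity"]

CALL_COLUMNS = [
    "rsid", "tf", "allele", "allele_label",
    "ref_K", "alt_K", "fold_change", "direction",
]


def _direction(fold: float, threshold: float) -> str:
    if fold >= threshold:
        return "increase"
    if fold <= 1.0 / threshold:
        return "decrease"
    return "none"


def call_allelic(
    fits: pd.DataFrame,
    variants: Sequence[VariantRecord],
    threshold: float = 2.0,
) -> pd.DataFrame:
    """One call per (variant, alternate allele, tf).

    ``fits`` needs columns rsid, allele, K_nM_inv, converged (and optionally
    tf).  Unconverged alleles produce no call; variants without a converged
    reference-allele fit are skipped with a warning.
    """
    if threshold <= 1:
        raise ValueError("fold threshold must exceed 1")
    by_rsid: Mapping[str, VariantRecord] = {v.rsid: v for v in variants}
    df = fits.copy()
    if "tf" not in df.columns:
        df["tf"] = ""
    df = df[df["converged"] & df["K_nM_inv"].notna()]
    rows = []
    for (rsid, tf), sub in df.groupby(["rsid", "tf"], sort=True):
        variant = by_rsid.get(rsid)
        if variant is None:
            warnings.warn(f"{rsid}: not in the variant set, skipped")
            continue
        ks = dict(zip(sub["allele"], sub["K_nM_inv"]))
        ref_K = ks.get(variant.ref_allele)
        if ref_K is None:
            warnings.warn(f"{rsid}/{tf}: reference allele fit missing, variant skipped")
            continue
        labels = allele_labels(variant)
        for allele in sorted(ks):
            if allele == variant.ref_allele:
                continue
            fold = ks[allele] / ref_K
            rows.append(
                {
                    "rsid": rsid,
                    "tf": tf,
                    "allele": allele,
                    "allele_label": labels[allele],
                    "ref_K": ref_K,
                    "alt_K": ks[allele],
                    "fold_change": fold,
                    "direction": _direction(fold, threshold),
                }
            )
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def intersect_tfs(calls_by_tf: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-variant set of TFs with allelic binding.

    A variant counts as allelic for a TF when any of its alternate alleles
    has direction != none.  Returns a DataFrame with columns rsid, tfs
    (sorted tuple), n_tfs; variants hit by >= 2 TFs are flagged ``multi_tf``.
    """
    hit: dict[str, set[str]] = {}
    for tf, calls in calls_by_tf.items():
        if calls.empty:
            continue
        allelic = calls.loc[calls["direction"] != "none", "rsid"].unique()
        for rsid in allelic:
            hit.setdefault(rsid, set()).add(tf)
    rows = [
        {"rsid": rsid, "tfs": tuple(sorted(tfs)), "n_tfs": len(tfs), "multi_tf": len(tfs) >= 2}
        for rsid, tfs in sorted(hit.items())
    ]
    return pd.DataFrame(rows, columns=["rsid", "tfs", "n_tfs", "multi_tf"])


def top_n_by_affinity(fits: pd.DataFrame, n: int) -> pd.DataFrame:
    """Top-n sequences by fitted K, descending; deterministic tie-break.

    Ties are broken by rsid then allele lexicographically.  Asking for more
    sequences than exist returns everything with a warning.
    """
    df = fits[fits["converged"] & fits["K_nM_inv"].notna()].copy()
    if n > len(df):
        warnings.warn(f"requested top {n} but only {len(df)} fitted sequences available")
        n = len(df)
    df = df.sort_values(
        ["K_nM_inv", "rsid", "allele"], ascending=[False, True, True], kind="mergesort"
    )
    return df.head(n).reset_index(drop=True)
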