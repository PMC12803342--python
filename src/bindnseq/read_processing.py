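"""Read 1 processing: window extraction, catalog matching, allele counting.

Reads are anchored on the constant right adapter; the 44 bases immediately
upstream are the UMI-flanked variant window.  After stripping the 2-nt UMIs
the inner 40-mer is matched against the library catalog with a wildcard at
the SNP position, so any base sequenced at position 20 (1-based) is counted
as that variant's allele.  Rejected reads are tallied per reason rather than
raised — a discarded read is an expected outcome of sequencing noise.
"""

from __future__ import annotations

import gzip
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .library_model import (
    BASES,
    DEFAULT_DESIGN,
    OligoDesign,
    VariantRecord,
    permute_alleles,
)

__all__ = [
    "SampleKey",
    "ReadCountTable",
    "CatalogIndex",
    "build_catalog",
    "extract_window",
    "assign_allele",
    "count_fastq",
    "read_sample_sheet",
    "to_ppm",
]

FRACTIONS = ("bound", "unbound", "library")

COUNT_COLUMNS = ["rsid", "allele", "tf", "fraction", "concentration_nM", "replicate", "count"]


@dataclass(frozen=True, order=True)
class SampleKey:
    """Identity of one sequenced sample (one gel band or the input library)."""

    tf: str
    fraction: str
    concentration_nM: Optional[float]
    replicate: str

    def __post_init__(self):
        if self.fraction not in FRACTIONS:
            raise ValueError(f"fraction must be one of {FRACTIONS}, got {self.fraction!r}")
        if self.fraction == "library":
            if self.concentration_nM is not None:
                raise ValueError("library samples carry no concentration")
        else:
            if self.concentration_nM is None or self.concentration_nM < 0:
                raise ValueError(
                    f"{self.fraction} sample needs a non-negative concentration, "
                    f"got {self.concentration_nM!r}"
                )

    @property
    def conc_value(self) -> float:
        """Concentration as a float, NaN for library samples (for DataFrames)."""
        return math.nan if self.concentration_nM is None else float(self.concentration_nM)


def _key_from_row(tf, fraction, concentration_nM, replicate) -> SampleKey:
    conc = None if (fraction == "library" or pd.isna(concentration_nM)) else float(concentration_nM)
    return SampleKey(str(tf), str(fraction), conc, str(replicate))


class ReadCountTable:
    """Counts per (rsid, allele, sample), totals, and per-reason discards.

    ``totals[key]`` is the number of reads *assigned* to the catalog in that
    sample — this is the N used for ppm scaling and pseudo-counts (discarded
    reads never contribute; the raw-read total is recoverable by adding the
    discard counts).
    """

    def __init__(
        self,
        counts: Mapping[tuple[str, str, SampleKey], int] | None = None,
        discarded: Mapping[SampleKey, Mapping[str, int]] | None = None,
    ):
        self.counts: dict[tuple[str, str, SampleKey], int] = dict(counts or {})
        self.discarded: dict[SampleKey, Counter] = {
            k: Counter(v) for k, v in (discarded or {}).items()
        }

    @property
    def samples(self) -> list[SampleKey]:
        keys = {k for (_, _, k) in self.counts} | set(self.discarded)
        return sorted(keys)

    def total(self, key: SampleKey) -> int:
        return sum(n for (_, _, k), n in self.counts.items() if k == key)

    @property
    def totals(self) -> dict[SampleKey, int]:
        out: dict[SampleKey, int] = {k: 0 for k in self.samples}
        for (_, _, k), n in self.counts.items():
            out[k] = out.get(k, 0) + n
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "rsid": rsid,
                "allele": allele,
                "tf": k.tf,
                "fraction": k.fraction,
                "concentration_nM": k.conc_value,
                "replicate": k.replicate,
                "count": n,
            }
            for (rsid, allele, k), n in self.counts.items()
        ]
        df = pd.DataFrame(rows, columns=COUNT_COLUMNS)
        return df.sort_values(COUNT_COLUMNS[:-1], ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReadCountTable":
        table = cls()
        for row in df.itertuples(index=False):
            key = _key_from_row(row.tf, row.fraction, row.concentration_nM, row.replicate)
            table.counts[(str(row.rsid), str(row.allele), key)] = int(row.count)
        return table

    def discard_frame(self) -> pd.DataFrame:
        rows = [
            {
                "tf": k.tf,
                "fraction": k.fraction,
                "concentration_nM": k.conc_value,
                "replicate": k.replicate,
                "reason": reason,
                "count": n,
            }
            for k, reasons in self.discarded.items()
            for reason, n in sorted(reasons.items())
        ]
        return pd.DataFrame(
            rows, columns=["tf", "fraction", "concentration_nM", "replicate", "reason", "count"]
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "ReadCountTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# Catalog: wildcard-keyed index of the variant library
# ---------------------------------------------------------------------------

@dataclass
class CatalogIndex:
    """Lookup from SNP-masked 39-mers to rsids.

    The key is the 40-mer with the SNP-position base removed, so one key
    covers all four alleles of a variant.  Keys claimed by two rsids are
    recorded as collisions and never assigned (avoids silent double counting).
    """

    index: dict[str, str] = field(default_factory=dict)
    collisions: set[str] = field(default_factory=set)
    snp_position: int = 19

    def lookup(self, masked: str) -> Optional[str]:
        if masked in self.collisions:
            return None
        return self.index.get(masked)


def build_catalog(variants: Sequence[VariantRecord]) -> CatalogIndex:
    import warnings

    pos = variants[0].snp_position if variants else 19
    cat = CatalogIndex(snp_position=pos)
    for v in variants:
        if v.snp_position != pos:
            raise ValueError("all variants in a catalog must share snp_position")
        masked = v.context40[:pos] + v.context40[pos + 1:]
        prev = cat.index.get(masked)
        if prev is not None and prev != v.rsid:
            cat.collisions.add(masked)
            warnings.warn(
                f"catalog collision: {prev} and {v.rsid} share a masked context; "
                "reads matching it will be discarded"
            )
        else:
            cat.index[masked] = v.rsid
    return cat


# ---------------------------------------------------------------------------
# Per-read operations
# ---------------------------------------------------------------------------

def extract_window(
    read: str,
    design: OligoDesign = DEFAULT_DESIGN,
    anchor_length: int | None = None,
) -> Optional[str]:
    """Return the 44-mer immediately preceding the right-adapter anchor.

    The anchor must start at offset >= window length (44); otherwise there
    are not enough upstream bases and the read is unusable.  ``anchor_length``
    trims the anchor to its first k nt to tolerate 3' quality loss (default:
    the full adapter).
    """
    k = len(design.right_adapter) if anchor_length is None else anchor_length
    anchor = design.right_adapter[:k]
    wlen = design.window_length
    idx = read.find(anchor, wlen)
    if idx < 0:
        return None
    return read[idx - wlen: idx]


def assign_allele(
    window44: str, catalog: CatalogIndex, design: OligoDesign = DEFAULT_DESIGN
) -> tuple[Optional[tuple[str, str]], Optional[str]]:
    """Strip UMIs, match against the catalog, and read off the allele.

    Returns ``((rsid, allele), None)`` on success or ``(None, reason)`` with
    reason in {"no_match", "ambiguous_base", "collision"}.
    """
    u = design.umi_length
    inner = window44[u: len(window44) - u]
    pos = catalog.snp_position
    base = inner[pos]
    if base not in BASES:
        return None, "ambiguous_base"
    masked = inner[:pos] + inner[pos + 1:]
    if masked in catalog.collisions:
        return None, "collision"
    rsid = catalog.index.get(masked)
    if rsid is None:
        return None, "no_match"
    return (rsid, base), None


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_sample_sheet(path) -> list[tuple[str, SampleKey]]:
    """Parse a sample sheet TSV: file, tf, fraction, concentration_nM, replicate."""
    df = pd.read_csv(path, sep="\t", dtype={"file": str})
    required = ["file", "tf", "fraction", "concentration_nM", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: sample sheet missing column(s) {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append((row.file, _key_from_row(row.tf, row.fraction, row.concentration_nM, row.replicate)))
    return out


def count_fastq(
    samples: Iterable[tuple[str, SampleKey]],
    catalog: CatalogIndex,
    design: OligoDesign = DEFAULT_DESIGN,
    anchor_length: int | None = None,
) -> ReadCountTable:
    """Count allele-assigned reads for every (FASTQ file, sample) pair.

    Each FASTQ is associated with exactly one sample; a sample appearing
    twice is an error.  The result is independent of read order.
    """
    table = ReadCountTable()
    seen: set[SampleKey] = set()
    for path, key in samples:
        if key in seen:
            raise ValueError(f"sample {key} assigned to more than one FASTQ file")
        seen.add(key)
        table.discarded.setdefault(key, Counter())
        try:
            fh = _open_text(path)
        except OSError as e:
            raise OSError(f"cannot read FASTQ {path}: {e}") from e
        with fh:
            try:
                for _title, seq, _qual in FastqGeneralIterator(fh):
                    window = extract_window(seq.upper(), design, anchor_length)
                    if window is None:
                        table.discarded[key]["no_anchor"] += 1
                        continue
                    hit, reason = assign_allele(window, catalog, design)
                    if hit is None:
                        table.discarded[key][reason] += 1
                        continue
                    rsid, allele = hit
                    ck = (rsid, allele, key)
                    table.counts[ck] = table.counts.get(ck, 0) + 1
            except ValueError as e:
                raise ValueError(f"malformed FASTQ {path}: {e}") from e
    return table


def to_ppm(table: ReadCountTable) -> pd.DataFrame:
    """Scale counts to parts per million of assigned reads per sample.

    Zero-total samples are flagged (``ppm`` left NaN) rather than divided.
    """
    df = table.to_frame()
    totals = table.totals
    tot = df.apply(
        lambda r: totals[_key_from_row(r.tf, r.fraction, r.concentration_nM, r.replicate)],
        axis=1,
    ) if len(df) else pd.Series(dtype=float)
    df["total"] = tot
    df["ppm"] = float("nan")
    ok = df["total"] > 0
    df.loc[ok, "ppm"] = df.loc[ok, "count"] / df.loc[ok, "total"] * 1e6
    return df
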