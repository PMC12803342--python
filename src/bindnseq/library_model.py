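"""Oligo library model: variant records, allele permutation, oligo assembly.

The assay interrogates SNPs embedded in 40 bp of genomic context (the variant
at 0-based position 19: 19 bases upstream, 20 downstream).  Each 40-mer is
decorated with a 2-nt degenerate UMI on each side plus constant sequencing
adapters, giving a 102-bp oligo with the default design.  Every variant is
permuted to all four central bases so that non-risk alleles are assayed too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "BASES",
    "VariantRecord",
    "OligoDesign",
    "DEFAULT_DESIGN",
    "permute_alleles",
    "build_oligo",
    "read_manifest",
    "write_manifest",
    "write_oligo_fasta",
]

BASES = ("A", "C", "G", "T")

DEFAULT_LEFT_ADAPTER = "TCCCTACACGACGCTCTTCCGATCT"
DEFAULT_RIGHT_ADAPTER = "GATCGGAAGAGCACACGTCTGAACTCCAGTCAC"

#: 0-based index of the SNP within the 40-bp context (printed 1-based as 20).
SNP_POSITION = 19


class ManifestError(ValueError):
    """Raised for malformed variant manifests or invalid variant records."""


@dataclass(frozen=True)
class VariantRecord:
    """One SNP with its 40-bp reference context and the alternate alleles.

    ``alt_alleles`` is ordered: the first entry is the GWAS tag allele where
    known, the rest follow in A<C<G<T order.  ``snp_position`` is 0-based.
    """

    rsid: str
    context40: str
    ref_allele: str
    alt_alleles: tuple[str, ...]
    snp_position: int = SNP_POSITION

    def __post_init__(self) -> None:
        validate_variant(self)


def validate_variant(v: VariantRecord) -> None:
    if len(v.context40) != 40:
        raise ManifestError(
            f"{v.rsid}: context must be 40 nt, got {len(v.context40)}"
        )
    if not set(v.context40) <= set(BASES):
        bad = sorted(set(v.context40) - set(BASES))
        raise ManifestError(f"{v.rsid}: non-ACGT base(s) {bad} in context")
    if not 0 <= v.snp_position < 40:
        raise ManifestError(f"{v.rsid}: snp_position {v.snp_position} out of range")
    if v.ref_allele not in BASES:
        raise ManifestError(f"{v.rsid}: invalid ref allele {v.ref_allele!r}")
    if v.context40[v.snp_position] != v.ref_allele:
        raise ManifestError(
            f"{v.rsid}: context base {v.context40[v.snp_position]!r} at SNP "
            f"position does not match ref allele {v.ref_allele!r}"
        )
    if not 1 <= len(v.alt_alleles) <= 3:
        raise ManifestError(f"{v.rsid}: need 1-3 alt alleles, got {v.alt_alleles}")
    for a in v.alt_alleles:
        if a not in BASES:
            raise ManifestError(f"{v.rsid}: invalid alt allele {a!r}")
    if v.ref_allele in v.alt_alleles:
        raise ManifestError(f"{v.rsid}: ref allele listed among alt alleles")
    if len(set(v.alt_alleles)) != len(v.alt_alleles):
        raise ManifestError(f"{v.rsid}: duplicate alt alleles")


@dataclass(frozen=True)
class OligoDesign:
    """Constant decoration applied around the 40-bp variant window."""

    left_adapter: str = DEFAULT_LEFT_ADAPTER
    right_adapter: str = DEFAULT_RIGHT_ADAPTER
    umi_length: int = 2

    @property
    def oligo_length(self) -> int:
        return len(self.left_adapter) + len(self.right_adapter) + 40 + 2 * self.umi_length

    @property
    def window_length(self) -> int:
        """Length of the UMI-flanked variant window (44 with 2-nt UMIs)."""
        return 40 + 2 * self.umi_length


DEFAULT_DESIGN = OligoDesign()


def allele_order(variant: VariantRecord) -> tuple[str, ...]:
    """Deterministic allele order: ref, tag alt, remaining bases A<C<G<T."""
    tag = variant.alt_alleles[0]
    rest = sorted(b for b in BASES if b not in (variant.ref_allele, tag))
    return (variant.ref_allele, tag, *rest)


def allele_labels(variant: VariantRecord) -> dict[str, str]:
    """Map allele base -> label (Ref, Alt1, Alt2, Alt3) in canonical order."""
    order = allele_order(variant)
    return {order[0]: "Ref", **{b: f"Alt{i}" for i, b in enumerate(order[1:], 1)}}


def permute_alleles(variant: VariantRecord) -> list[tuple[str, str]]:
    """Return the four (allele, 40-mer) pairs for a variant.

    The reference pair comes first, then the GWAS tag allele, then the
    remaining bases alphabetically; each 40-mer differs from the reference
    context only at the SNP position.
    """
    validate_variant(variant)
    ctx, pos = variant.context40, variant.snp_position
    return [(b, ctx[:pos] + b + ctx[pos + 1:]) for b in allele_order(variant)]


def build_oligo(
    window40: str,
    design: OligoDesign = DEFAULT_DESIGN,
    umis: tuple[str, str] = ("NN", "NN"),
) -> str:
    """Assemble the full oligo: left adapter + UMI + window + UMI + right adapter."""
    if len(window40) != 40:
        raise ManifestError(f"window must be 40 nt, got {len(window40)}")
    umi1, umi2 = umis
    if len(umi1) != design.umi_length or len(umi2) != design.umi_length:
        raise ManifestError(
            f"UMIs must be {design.umi_length} nt, got {umi1!r}, {umi2!r}"
        )
    return design.left_adapter + umi1 + window40 + umi2 + design.right_adapter


MANIFEST_COLUMNS = ["rsid", "context40", "snp_position", "ref_allele", "alt_alleles"]


def read_manifest(path) -> list[VariantRecord]:
    """Read a TSV variant manifest into validated records.

    Columns: rsid, context40, snp_position (0-based), ref_allele,
    alt_alleles (comma-separated, tag allele first).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"{path}: missing manifest column(s) {missing}")
    records: list[VariantRecord] = []
    seen: dict[str, int] = {}
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        rsid = row.rsid
        if rsid in seen:
            raise ManifestError(
                f"{path}: duplicate rsid {rsid!r} at line {idx} (first at line {seen[rsid]})"
            )
        seen[rsid] = idx
        try:
            rec = VariantRecord(
                rsid=rsid,
                context40=row.context40,
                snp_position=int(row.snp_position),
                ref_allele=row.ref_allele,
                alt_alleles=tuple(row.alt_alleles.split(",")),
            )
        except (ManifestError, AttributeError, ValueError) as e:
            raise ManifestError(f"{path}: line {idx}: {e}") from e
        records.append(rec)
    warn_duplicate_contexts(records)
    return records


def warn_duplicate_contexts(records: Sequence[VariantRecord]) -> list[tuple[str, str]]:
    """Warn about rsid pairs sharing an identical 40-bp context.

    Duplicates are legal (counting is keyed by sequence) but ambiguous reads
    cannot be attributed to a single rsid, so they are surfaced loudly.
    """
    by_ctx: dict[str, list[str]] = {}
    for r in records:
        by_ctx.setdefault(r.context40, []).append(r.rsid)
    dups = [(ids[0], other) for ids in by_ctx.values() if len(ids) > 1 for other in ids[1:]]
    for a, b in dups:
        warnings.warn(f"variants {a} and {b} share an identical 40-bp context")
    return dups


def write_manifest(records: Iterable[VariantRecord], path) -> None:
    rows = [
        {
            "rsid": r.rsid,
            "context40": r.context40,
            "snp_position": r.snp_position,
            "ref_allele": r.ref_allele,
            "alt_alleles": ",".join(r.alt_alleles),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


def write_oligo_fasta(
    records: Iterable[VariantRecord],
    path,
    design: OligoDesign = DEFAULT_DESIGN,
    umis: tuple[str, str] = ("NN", "NN"),
) -> None:
    """Export full oligos, one FASTA record per allele, id ``rsid|allele``."""
    with open(path, "w") as fh:
        for rec in records:
            for allele, window in permute_alleles(rec):
                fh.write(f">{rec.rsid}|{allele}\n{build_oligo(window, design, umis)}\n")
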