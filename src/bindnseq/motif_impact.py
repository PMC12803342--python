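"""PWM scanning of ref/alt windows and motif creation/disruption calls.

Each variant's reference and alternate 40-mers are scored against a PWM as
log2 odds over a background, on both strands and at every offset.  A motif
is "present" in a sequence when its best window reaches a fraction of the
PWM's maximum achievable score.  A variant *creates* a motif when the
alternate allele has the motif, the reference does not, and the SNP lies
inside the alternate's best window; *disrupts* is the mirror image.
Positional histograms then ask where within the motif the SNPs fall,
stratified by the direction of the binding change.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .library_model import BASES, VariantRecord, permute_alleles

__all__ = [
    "PWM",
    "MotifHit",
    "ImpactCall",
    "read_meme_minimal",
    "write_meme_minimal",
    "log_odds",
    "max_score",
    "scan_best",
    "classify_impact",
    "impact_frame",
    "position_histogram",
]

#: probability floor added before renormalizing each PWM row (MEME matrices
#: may contain exact zeros, which would give -inf log odds)
PROB_FLOOR = 1e-3

_BASE_IDX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PWM:
    """Position weight matrix: per-position base probabilities plus background."""

    name: str
    matrix: np.ndarray            # (width, 4), columns A C G T
    background: np.ndarray = None  # (4,)
    nsites: int = 0

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise ValueError(f"{self.name}: matrix must be (width, 4)")
        bg = np.full(4, 0.25) if self.background is None else np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0, atol=1e-4):
            raise ValueError(f"{self.name}: background must be 4 probabilities summing to 1")
        if np.any(m < 0) or not np.allclose(m.sum(axis=1), 1.0, atol=1e-3):
            raise ValueError(f"{self.name}: matrix rows must be probabilities summing to 1")
        # floor and renormalize so log-odds stay finite
        m = (m + PROB_FLOOR) / (1.0 + 4 * PROB_FLOOR)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "background", bg)

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def reverse_complement(self) -> "PWM":
        return PWM(
            name=self.name,
            # reversing both axes maps position p, base b -> W-1-p, complement(b)
            matrix=self.matrix[::-1, ::-1] * (1.0 + 4 * PROB_FLOOR) - PROB_FLOOR,
            background=self.background[::-1].copy(),
            nsites=self.nsites,
        )


@dataclass(frozen=True)
class MotifHit:
    """Best-scoring PWM window within a sequence (forward coordinates)."""

    offset: int
    strand: str
    score: float
    window: str


@dataclass(frozen=True)
class ImpactCall:
    rsid: str
    pwm: str
    ref_hit: MotifHit
    alt_hit: MotifHit
    snp_in_ref_hit: bool
    snp_in_alt_hit: bool
    category: str            # created / disrupted / unaffected
    delta_score: float
    ref_allele: str = ""
    alt_allele: str = ""


def read_meme_minimal(path) -> list[PWM]:
    """Parse PWMs from a MEME minimal-format motif file.

    Parsed directly at full float precision (generic motif readers that
    convert the letter-probability matrix to integer counts quantize the
    probabilities to multiples of 1/nsites).
    """
    background = np.full(4, 0.25)
    pwms: list[PWM] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not any(l.strip().lower().startswith("meme version") for l in lines):
        raise ValueError(f"{path}: not a MEME minimal file (no 'MEME version' line)")
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("ALPHABET="):
            alphabet = line.split("=", 1)[1].strip()
            if alphabet != "ACGT":
                raise ValueError(f"{path}: unsupported alphabet {alphabet!r}")
        elif line.startswith("Background letter frequencies"):
            i += 1
            tokens: list[str] = []
            while i < len(lines) and lines[i].strip() and not lines[i].startswith("MOTIF"):
                tokens += lines[i].split()
                i += 1
            freqs = {tokens[j]: float(tokens[j + 1]) for j in range(0, len(tokens), 2)}
            background = np.array([freqs.get(b, 0.25) for b in BASES])
            continue
        elif line.startswith("MOTIF"):
            name = line.split(None, 2)[1] if len(line.split()) > 1 else f"motif_{len(pwms) + 1}"
            i += 1
            while i < len(lines) and not lines[i].strip().startswith("letter-probability"):
                if lines[i].strip().startswith("MOTIF"):
                    break
                i += 1
            if i >= len(lines) or not lines[i].strip().startswith("letter-probability"):
                raise ValueError(f"{path}: motif {name}: no letter-probability matrix")
            header = lines[i]
            fields = dict(re.findall(r"(\w+)=\s*(\S+)", header))
            width = int(fields["w"]) if "w" in fields else None
            nsites = int(float(fields.get("nsites", 0)))
            i += 1
            rows = []
            while i < len(lines):
                parts = lines[i].split()
                if len(parts) != 4:
                    break
                try:
                    rows.append([float(x) for x in parts])
                except ValueError:
                    break
                i += 1
                if width is not None and len(rows) == width:
                    break
            if not rows or (width is not None and len(rows) != width):
                raise ValueError(
                    f"{path}: motif {name}: expected {width} matrix rows near line {i + 1}"
                )
            try:
                pwms.append(PWM(name=name, matrix=np.array(rows),
                                background=background, nsites=nsites))
            except ValueError as e:
                raise ValueError(f"{path}: motif {name}: {e}") from e
            continue
        i += 1
    if not pwms:
        raise ValueError(f"{path}: no MOTIF blocks found")
    return pwms


def write_meme_minimal(pwms: Iterable[PWM], path) -> None:
    """Write PWMs in MEME minimal format.

    The stored matrix is un-floored back to the raw probabilities before
    writing, so write -> read recovers the same floored PWM.
    """
    pwms = list(pwms)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {p:.5f}" for b, p in zip(BASES, bg)) + "\n\n")
        for p in pwms:
            fh.write(f"MOTIF {p.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {p.width} "
                f"nsites= {max(p.nsites, 1)} E= 0\n"
            )
            raw = np.clip(p.matrix * (1.0 + 4 * PROB_FLOOR) - PROB_FLOOR, 0.0, 1.0)
            for row in raw:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def log_odds(pwm: PWM, kmer: str) -> Optional[float]:
    """Sum of log2(p/background) over positions; None for non-ACGT windows."""
    if len(kmer) != pwm.width:
        raise ValueError(f"k-mer length {len(kmer)} != motif width {pwm.width}")
    try:
        idx = [_BASE_IDX[b] for b in kmer]
    except KeyError:
        return None
    rows = np.arange(pwm.width)
    return float(np.sum(np.log2(pwm.matrix[rows, idx] / pwm.background[idx])))


def max_score(pwm: PWM) -> float:
    """Maximum achievable log-odds score (consensus against background)."""
    return float(np.sum(np.max(np.log2(pwm.matrix / pwm.background[None, :]), axis=1)))


def scan_best(sequence: str, pwm: PWM) -> Optional[MotifHit]:
    """Best-scoring window over both strands and all offsets.

    Ties go to the smallest offset, + strand before -.  Returns None when no
    window is scorable (all contain non-ACGT bases).
    """
    w = pwm.width
    if len(sequence) < w:
        raise ValueError("sequence shorter than motif width")
    best: Optional[MotifHit] = None
    for offset in range(len(sequence) - w + 1):
        kmer = sequence[offset: offset + w]
        for strand, probe in (("+", kmer), ("-", revcomp(kmer))):
            score = log_odds(pwm, probe)
            if score is None:
                continue
            if best is None or score > best.score:
                best = MotifHit(offset=offset, strand=strand, score=score, window=kmer)
    return best


def _snp_in(hit: Optional[MotifHit], snp_position: int, width: int) -> bool:
    # - strand hits cover the same forward-strand interval, so overlap is
    # evaluated in forward coordinates either way
    return hit is not None and hit.offset <= snp_position < hit.offset + width


def classify_impact(
    variant: VariantRecord,
    allele: str,
    pwm: PWM,
    presence_threshold: float = 0.8,
) -> ImpactCall:
    """Classify one (variant, alternate allele) against one PWM.

    ``presence_threshold`` is the fraction of the PWM's maximum achievable
    score a window must reach for the motif to count as present.
    """
    windows = dict(permute_alleles(variant))
    if allele not in windows:
        raise ValueError(f"{variant.rsid}: allele {allele!r} not a valid base")
    ref_seq = windows[variant.ref_allele]
    alt_seq = windows[allele]
    ref_hit = scan_best(ref_seq, pwm)
    alt_hit = scan_best(alt_seq, pwm)
    cutoff = presence_threshold * max_score(pwm)
    ref_present = ref_hit is not None and ref_hit.score >= cutoff
    alt_present = alt_hit is not None and alt_hit.score >= cutoff
    in_ref = _snp_in(ref_hit, variant.snp_position, pwm.width)
    in_alt = _snp_in(alt_hit, variant.snp_position, pwm.width)
    if alt_present and not ref_present and in_alt:
        category = "created"
    elif ref_present and not alt_present and in_ref:
        category = "disrupted"
    else:
        category = "unaffected"
    delta = (alt_hit.score if alt_hit else float("-inf")) - (
        ref_hit.score if ref_hit else float("-inf")
    )
    if ref_hit is None and alt_hit is None:
        delta = 0.0
    return ImpactCall(
        rsid=variant.rsid, pwm=pwm.name,
        ref_hit=ref_hit, alt_hit=alt_hit,
        snp_in_ref_hit=in_ref, snp_in_alt_hit=in_alt,
        category=category, delta_score=delta,
        ref_allele=variant.ref_allele, alt_allele=allele,
    )


def impact_frame(calls: Iterable[ImpactCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "rsid": c.rsid, "pwm": c.pwm, "allele": c.alt_allele,
                "category": c.category,
                "ref_score": c.ref_hit.score if c.ref_hit else np.nan,
                "alt_score": c.alt_hit.score if c.alt_hit else np.nan,
                "delta_score": c.delta_score,
                "ref_offset": c.ref_hit.offset if c.ref_hit else -1,
                "ref_strand": c.ref_hit.strand if c.ref_hit else ".",
                "alt_offset": c.alt_hit.offset if c.alt_hit else -1,
                "alt_strand": c.alt_hit.strand if c.alt_hit else ".",
                "snp_in_ref_hit": c.snp_in_ref_hit,
                "snp_in_alt_hit": c.snp_in_alt_hit,
            }
        )
    return pd.DataFrame(rows)


def _motif_position(hit: MotifHit, snp_position: int, width: int) -> int:
    """1-based position of the SNP within the motif, along the hit's strand."""
    if hit.strand == "+":
        return snp_position - hit.offset + 1
    return hit.offset + width - snp_position


def position_histogram(
    calls: Sequence[ImpactCall],
    directions: Sequence[str],
    width: int,
    snp_position: int = 19,
) -> pd.DataFrame:
    """Where within the motif do impactful SNPs fall, by binding direction.

    For created motifs the alternate allele's hit is used, for disrupted the
    reference allele's; unaffected calls and calls whose SNP lies outside
    the relevant hit are excluded.  Column totals equal the number of
    SNP-overlapping affected calls.
    """
    if len(calls) != len(directions):
        raise ValueError("one direction per call required")
    hist = pd.DataFrame(
        0, index=pd.RangeIndex(1, width + 1, name="motif_position"),
        columns=["increase", "decrease"],
    )
    for call, direction in zip(calls, directions):
        if call.category == "created":
            hit, ok = call.alt_hit, call.snp_in_alt_hit
        elif call.category == "disrupted":
            hit, ok = call.ref_hit, call.snp_in_ref_hit
        else:
            continue
        if not ok or direction not in ("increase", "decrease"):
            continue
        pos = _motif_position(hit, snp_position, width)
        hist.loc[pos, direction] += 1
    return hist
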