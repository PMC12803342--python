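"""Ground-truth simulator: libraries, Poisson count tables, FASTQ reads.

The generator is the model's generative twin: per-sequence affinities K and
well-retention w produce occupancies, self-consistent denominators turn
those into expected counts at each sample's sequencing depth, and counts
are drawn independently Poisson per cell.  Defaults mirror the assay's
design: two replicates at 0/100/500/1000/1500/2000/3000 nM, 2x10^6 reads
per sample, K log-uniform over [1e-4, 1e-2] nM^-1 (Kd 100 nM - 10 uM,
spanning weak to near-saturating binding across the series), w = 0, and
symmetric-Dirichlet library composition.

The 0 nM bound lane is modelled as non-specific carryover with library
composition (the gel's zero-protein bound band contains material, which is
what the baseline QC ratios are computed from); setting
``zero_bound_background=False`` gives the pure model's empty lane instead.

Every draw flows from the single seed; same seed, same truth, same counts,
byte-identical FASTQ.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .affinity import ConcentrationSeries, DEFAULT_CONCENTRATIONS, occupancy, occupancy_with_well
from .library_model import BASES, DEFAULT_DESIGN, OligoDesign, VariantRecord, permute_alleles
from .read_processing import ReadCountTable, SampleKey

__all__ = ["SimulationTruth", "simulate_truth", "simulate_counts", "simulate_fastq"]

DEFAULT_DEPTH = 2e6
DEFAULT_REPLICATES = ("R1", "R2")


@dataclass
class SimulationTruth:
    """Everything the generator decided: the answer key for recovery tests."""

    variants: list[VariantRecord]
    K: dict[tuple[str, str], float]
    w: dict[tuple[str, str], float]
    library_fractions: dict[tuple[str, str], float]
    series: ConcentrationSeries
    depths: dict[SampleKey, float]
    seed: int
    planted: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        total = sum(self.library_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"library fractions sum to {total}, not 1")
        if any(k <= 0 for k in self.K.values()):
            raise ValueError("all K must be positive")
        if any(d <= 0 for d in self.depths.values()):
            raise ValueError("all depths must be positive")

    @property
    def sequences(self) -> list[tuple[str, str]]:
        return sorted(self.K)

    def truth_frame(self) -> pd.DataFrame:
        planted = {}
        if len(self.planted):
            planted = dict(zip(zip(self.planted["rsid"], self.planted["allele"]),
                               self.planted["fold"]))
        return pd.DataFrame(
            [
                {
                    "rsid": r, "allele": a, "K": self.K[(r, a)], "w": self.w[(r, a)],
                    "fraction": self.library_fractions[(r, a)],
                    "planted_fold": planted.get((r, a), 1.0),
                }
                for r, a in self.sequences
            ]
        )


def _random_context(rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(BASES), size=40))


def _draw(law, rng: np.random.Generator, n: int) -> np.ndarray:
    """Evaluate a named distribution: ("constant", v), ("log_uniform", lo, hi),
    or ("uniform", lo, hi)."""
    kind = law[0]
    if kind == "constant":
        return np.full(n, float(law[1]))
    if kind == "log_uniform":
        lo, hi = float(law[1]), float(law[2])
        if not 0 < lo < hi:
            raise ValueError(f"log_uniform needs 0 < lo < hi, got {law}")
        return 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), size=n)
    if kind == "uniform":
        return rng.uniform(float(law[1]), float(law[2]), size=n)
    raise ValueError(f"unknown law {law!r}")


def simulate_truth(
    n_variants: int,
    seed: int,
    K_law: tuple = ("log_uniform", 1e-4, 1e-2),
    w_law: tuple = ("constant", 0.0),
    fraction_alpha: float = 10.0,
    allele_mode: str = "independent",
    n_planted: int = 0,
    plant_fold: float = 4.0,
    plant_consensus: Optional[str] = None,
    tf: str = "TF1",
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS,
    replicates: Sequence[str] = DEFAULT_REPLICATES,
    depth: float = DEFAULT_DEPTH,
) -> SimulationTruth:
    """Draw a reproducible ground truth.

    ``allele_mode`` "independent" gives every allele sequence its own K from
    ``K_law``; "shared" gives all four alleles of a variant the same K, so
    fold changes are exactly 1 unless planted.  The first ``n_planted``
    variants get their tag alternate allele's K multiplied by ``plant_fold``.
    With ``plant_consensus``, planted variants embed that motif (broken by
    the reference base, completed by the tag alternate) around the SNP.
    """
    if allele_mode not in ("independent", "shared"):
        raise ValueError(f"unknown allele_mode {allele_mode!r}")
    if n_planted > n_variants:
        raise ValueError("cannot plant more variants than exist")
    rng = np.random.default_rng(seed)
    variants: list[VariantRecord] = []
    seen_ctx: set[str] = set()
    for i in range(n_variants):
        planted_here = i < n_planted and plant_consensus is not None
        while True:
            ctx = _random_context(rng)
            if planted_here:
                cons = plant_consensus.upper()
                wlen = len(cons)
                # SNP somewhere inside the motif, motif fully inside the window
                p = int(rng.integers(0, wlen))
                start = 19 - p
                if not 0 <= start <= 40 - wlen:
                    continue
                ctx = ctx[:start] + cons + ctx[start + wlen:]
                # reference base breaks the consensus
                ref = str(rng.choice([b for b in BASES if b != cons[p]]))
                ctx = ctx[:19] + ref + ctx[20:]
            if ctx not in seen_ctx:
                seen_ctx.add(ctx)
                break
        ref = ctx[19]
        alts = [b for b in BASES if b != ref]
        if planted_here:
            tag = plant_consensus.upper()[p]
            alts = [tag] + sorted(b for b in alts if b != tag)
        variants.append(VariantRecord(rsid=f"rs{i + 1:06d}", context40=ctx,
                                      ref_allele=ref, alt_alleles=tuple(alts)))

    sequences = [(v.rsid, a) for v in variants for a, _ in permute_alleles(v)]
    S = len(sequences)
    if allele_mode == "independent":
        K = dict(zip(sequences, _draw(K_law, rng, S)))
    else:
        perK = _draw(K_law, rng, n_variants)
        K = {
            (v.rsid, a): perK[i]
            for i, v in enumerate(variants)
            for a, _ in permute_alleles(v)
        }
    w = dict(zip(sequences, np.clip(_draw(w_law, rng, S), 0.0, 1.0)))
    fractions = rng.dirichlet(np.full(S, fraction_alpha))
    library_fractions = dict(zip(sequences, fractions / fractions.sum()))

    planted_rows = []
    for v in variants[:n_planted]:
        tag = v.alt_alleles[0]
        K[(v.rsid, tag)] = K[(v.rsid, tag)] * plant_fold
        planted_rows.append({"rsid": v.rsid, "allele": tag, "fold": plant_fold})

    series = ConcentrationSeries(values=tuple(sorted(float(c) for c in concentrations)))
    depths: dict[SampleKey, float] = {}
    for rep in replicates:
        depths[SampleKey(tf, "library", None, rep)] = depth
        for c in series.values:
            depths[SampleKey(tf, "bound", c, rep)] = depth
            depths[SampleKey(tf, "unbound", c, rep)] = depth
    return SimulationTruth(
        variants=variants, K=K, w=w, library_fractions=library_fractions,
        series=series, depths=depths, seed=seed,
        planted=pd.DataFrame(planted_rows, columns=["rsid", "allele", "fold"]),
    )


def self_consistent_denominators(truth: SimulationTruth) -> tuple[dict, dict]:
    """D_j = sum_i f_i*(1-w_i)*P_ij and D_uj = sum_i f_i*(1-P_ij): with these,
    expected bound/unbound totals equal the nominal depths."""
    seqs = truth.sequences
    f = np.array([truth.library_fractions[s] for s in seqs])
    K = np.array([truth.K[s] for s in seqs])
    w = np.array([truth.w[s] for s in seqs])
    D, Du = {}, {}
    for c in truth.series.values:
        P = occupancy(K, c)
        D[c] = float(np.sum(f * (1.0 - w) * P)) or 1.0
        Du[c] = float(np.sum(f * (1.0 - P))) or 1.0
    return D, Du


def simulate_counts(
    truth: SimulationTruth,
    mode: str = "poisson",
    zero_bound_background: bool = True,
) -> ReadCountTable:
    """Draw a count table from the truth (seeded by ``truth.seed``).

    "poisson" draws each cell independently (matching the likelihood
    exactly); "multinomial" fixes each sample's total at its depth and
    draws the composition (off-model but closer to a sequencer's behavior).
    """
    if mode not in ("poisson", "multinomial"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(np.random.SeedSequence((truth.seed, 1)))
    seqs = truth.sequences
    f = np.array([truth.library_fractions[s] for s in seqs])
    K = np.array([truth.K[s] for s in seqs])
    w = np.array([truth.w[s] for s in seqs])
    D, Du = self_consistent_denominators(truth)
    table = ReadCountTable()
    for key in sorted(truth.depths):
        depth = truth.depths[key]
        if key.fraction == "library":
            lam = depth * f
        elif key.fraction == "bound":
            c = key.concentration_nM
            if c == 0 and zero_bound_background:
                lam = depth * f          # non-specific carryover, library composition
            else:
                lam = depth * f / D[c] * occupancy_with_well(K, c, w)
        else:
            c = key.concentration_nM
            lam = depth * f / Du[c] * (1.0 - occupancy(K, c))
        if mode == "poisson":
            counts = rng.poisson(lam)
        else:
            total = lam.sum()
            counts = (
                rng.multinomial(int(round(depth)), lam / total)
                if total > 0 else np.zeros(len(seqs), dtype=int)
            )
        for (rsid, allele), n in zip(seqs, counts):
            if n > 0:
                table.counts[(rsid, allele, key)] = int(n)
        table.discarded.setdefault(key, Counter())
    return table


def _sample_filename(key: SampleKey) -> str:
    conc = "library" if key.concentration_nM is None else f"{key.concentration_nM:g}nM"
    return f"{key.tf}_{key.fraction}_{conc}_{key.replicate}.fastq"


def simulate_fastq(
    truth: SimulationTruth,
    counts: ReadCountTable,
    outdir,
    error_rate: float = 0.0,
    seed: Optional[int] = None,
    design: OligoDesign = DEFAULT_DESIGN,
    include_left_adapter: bool = True,
) -> Path:
    """Write one FASTQ per sample plus a sample sheet; returns the sheet path.

    Each counted read becomes a record: [left adapter] + random UMI + allele
    40-mer + random UMI + right adapter, with per-base substitution errors
    at ``error_rate`` and constant quality.  At error rate 0, re-counting
    the FASTQ reproduces the drawn counts exactly.
    """
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(
        np.random.SeedSequence((truth.seed if seed is None else seed, 2))
    )
    windows = {
        (v.rsid, a): win for v in truth.variants for a, win in permute_alleles(v)
    }
    base_arr = np.array(list(BASES))
    sheet_rows = []
    for key in counts.samples:
        fname = _sample_filename(key)
        per_seq = sorted(
            ((rsid, allele), n)
            for (rsid, allele, k), n in counts.counts.items()
            if k == key
        )
        with open(outdir / fname, "w") as fh:
            read_no = 0
            for (rsid, allele), n in per_seq:
                win = windows[(rsid, allele)]
                umis = rng.integers(0, 4, size=(n, 2, design.umi_length))
                for k in range(n):
                    read_no += 1
                    umi1 = "".join(base_arr[umis[k, 0]])
                    umi2 = "".join(base_arr[umis[k, 1]])
                    seq = umi1 + win + umi2 + design.right_adapter
                    if include_left_adapter:
                        seq = design.left_adapter + seq
                    if error_rate > 0:
                        chars = np.array(list(seq))
                        hit = rng.random(len(chars)) < error_rate
                        if hit.any():
                            chars[hit] = base_arr[rng.integers(0, 4, size=int(hit.sum()))]
                            seq = "".join(chars)
                    fh.write(f"@{key.tf}:{fname}:{read_no} {rsid}|{allele}\n")
                    fh.write(f"{seq}\n+\n{'I' * len(seq)}\n")
        sheet_rows.append(
            {
                "file": fname, "tf": key.tf, "fraction": key.fraction,
                "concentration_nM": key.conc_value, "replicate": key.replicate,
            }
        )
    sheet = outdir / "samples.tsv"
    pd.DataFrame(sheet_rows).to_csv(sheet, sep="\t", index=False)
    return sheet
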