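"""Shared fixtures: hand-built variants, count tables, and the designed QC case."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from bindnseq import ReadCountTable, SampleKey, VariantRecord
from bindnseq.library_model import BASES


@pytest.fixture
def toy_variant() -> VariantRecord:
    """SNP with a C reference on an otherwise all-A context."""
    return VariantRecord(
        rsid="rsTOY",
        context40="A" * 19 + "C" + "A" * 20,
        ref_allele="C",
        alt_alleles=("A", "G", "T"),
    )


def _ctx(rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(BASES), size=40))


def random_variants(n: int, seed: int = 0) -> list[VariantRecord]:
    rng = np.random.default_rng(seed)
    out, seen = [], set()
    while len(out) < n:
        ctx = _ctx(rng)
        if ctx in seen:
            continue
        seen.add(ctx)
        ref = ctx[19]
        alts = tuple(b for b in BASES if b != ref)
        out.append(VariantRecord(f"rs{len(out) + 1:05d}", ctx, ref, alts))
    return out


@pytest.fixture
def variants3() -> list[VariantRecord]:
    return random_variants(3, seed=42)


def make_table(sample_counts: dict[SampleKey, dict[tuple[str, str], int]]) -> ReadCountTable:
    """Build a ReadCountTable from {sample: {(rsid, allele): count}}."""
    table = ReadCountTable()
    for key, per_seq in sample_counts.items():
        table.discarded.setdefault(key, Counter())
        for (rsid, allele), n in per_seq.items():
            table.counts[(rsid, allele, key)] = int(n)
    return table


# ---------------------------------------------------------------------------
# Designed QC fixture: each sequence violates exactly the filters it is
# built to violate, with per-sample totals padded to exactly 10^6 reads so
# that ppm == raw count.
# ---------------------------------------------------------------------------

def designed_qc_table() -> tuple[ReadCountTable, pd.DataFrame]:
    """Three 4-allele variants plus a filler sequence; returns the table and
    the expected flag vector for the 12 designed sequences.

    v1: one allele per single-filter violation (ratio, low unbound, low
    library in one replicate, bound/unbound ratio).  v2: one allele with a
    library dropout in both replicates (fails 3 and 5), dragging its three
    healthy siblings down via filter 5.  v3: all healthy; one allele has
    poor 0 nM recovery, which flags but does not fail.
    """
    tf = "TFX"
    seqs = {f"v{i}": [(f"v{i}", b) for b in BASES] for i in (1, 2, 3)}
    s1, s2, s3, s4 = seqs["v1"]
    s5, s6, s7, s8 = seqs["v2"]
    s9, s10, s11, s12 = seqs["v3"]

    healthy = {"lib": 100, "u0": 100, "b0": 100}
    design = {
        s1: {"lib": 1000, "u0": 100, "b0": 100},          # u0/lib = 0.1 -> filter 1
        s2: {"lib": 10, "u0": 4, "b0": 4},                # u0 < 5 both reps -> filter 2
        s3: {"lib": (4, 10), "u0": 6, "b0": 6},           # lib < 5 in R1 only -> filter 3
        s4: {"lib": 10, "u0": 10, "b0": 60},              # b0/u0 = 6 -> filter 4
        s5: healthy, s7: healthy, s8: healthy,            # dragged down by s6 -> filter 5
        s6: {"lib": 4, "u0": 6, "b0": 6},                 # lib < 5 both reps -> filters 3+5
        s9: healthy, s10: healthy, s11: healthy,
        s12: {"lib": 1000, "u0": 300, "b0": 100},         # recovery 400 < 0.5*1000 -> flag only
    }

    def val(spec, field, rep):
        v = spec[field]
        return v[0 if rep == "R1" else 1] if isinstance(v, tuple) else v

    samples: dict[SampleKey, dict] = {}
    for rep in ("R1", "R2"):
        for field, key in (
            ("lib", SampleKey(tf, "library", None, rep)),
            ("u0", SampleKey(tf, "unbound", 0.0, rep)),
            ("b0", SampleKey(tf, "bound", 0.0, rep)),
        ):
            per = {s: val(spec, field, rep) for s, spec in design.items()}
            per[("vFILL", "A")] = 10**6 - sum(per.values())
            samples[key] = per
        # protein-positive samples: arbitrary values the filters must ignore
        for conc in (100.0, 3000.0):
            for frac in ("bound", "unbound"):
                per = {s: 7 for s in design}
                per[("vFILL", "A")] = 10**6 - sum(per.values())
                samples[SampleKey(tf, frac, conc, rep)] = per

    expected = pd.DataFrame(
        {
            "rsid": [s[0] for s in design],
            "allele": [s[1] for s in design],
            "filter1_unbound0_library_ratio": [s != s1 for s in design],
            "filter2_low_unbound0": [s != s2 for s in design],
            "filter3_low_library": [s not in (s3, s6) for s in design],
            "filter4_bound0_unbound0_ratio": [s != s4 for s in design],
            "filter5_base_representation": [s[0] != "v2" for s in design],
            "recovery_flag": [s in (s1, s12) for s in design],
        }
    ).set_index(["rsid", "allele"])
    expected["overall_pass"] = expected[
        [c for c in expected.columns if c.startswith("filter")]
    ].all(axis=1)
    return make_table(samples), expected


@pytest.fixture
def qc_case():
    return designed_qc_table()
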