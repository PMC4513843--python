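"""Ground-truthed synthetic sequencing data for the ribozyme assay.

Emulates the amplicon structure the assay sequences (adapter — barcode —
reverse-complemented RNA fragment — adapter): every variant of a library is
given a true cleavage fraction per condition, per-variant read depth is fixed
or Poisson, each read is cleaved with probability ``true_f`` (binomial
counts), and iid substitution errors at a per-base rate emulate sequencer
noise.  Everything is deterministic given the seed, down to byte-identical
FASTQ output, and a truth manifest records the parameters and drawn counts
so downstream estimates can be validated against ground truth.

Deliberately NOT modeled: PCR amplification bias, chimeras, RT dropout,
indels, quality-score structure (qualities are constant placeholders; the
classifier never uses them).
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .designs import LibraryDesign, Status, build_amplicon, enumerate_variants

_DNA = np.frombuffer(b"ACGT", dtype=np.uint8)
_PLACEHOLDER_QUALITY = "I"  # Phred 40; qualities are unused downstream


@dataclass(frozen=True)
class SimParams:
    """Read-simulation parameters.

    depth:
        Mean (Poisson) or exact (fixed) reads per variant and condition.
    depth_model:
        ``"fixed"`` or ``"poisson"``; Poisson emulates the per-variant depth
        spread of a real run.
    error_rate:
        Per-base iid substitution probability (uniform over the three
        alternative bases).
    read_length:
        Truncate reads to this many bases from the adapter_t end; None means
        full amplicons.
    seed:
        Master seed; all random streams derive from it.
    """

    depth: float = 1000
    depth_model: str = "fixed"
    error_rate: float = 0.0
    read_length: int | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.depth < 0:
            raise ValueError("depth must be nonnegative")
        if self.depth_model not in ("fixed", "poisson"):
            raise ValueError(f"unknown depth_model {self.depth_model!r}")


@dataclass
class TruthManifest:
    """Simulator ground truth: true cleavage fraction per (condition, variant)."""

    design_name: str
    true_f: dict[tuple[str, str], float]  # (condition, variant) -> fraction
    seed: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c, v, f) for (c, v), f in self.true_f.items()],
            columns=["condition", "variant", "true_f"],
        )


def draw_truth(
    design: LibraryDesign,
    distribution: "str | tuple | Mapping" = "uniform",
    seed: int = 0,
    conditions: Sequence[str] | None = None,
) -> TruthManifest:
    """Assign a true cleavage fraction to every variant and condition.

    ``distribution`` is ``"uniform"`` (uniform on [0,1]), ``("beta", a, b)``,
    or an explicit mapping.  An explicit mapping is either
    variant -> fraction (applied to every condition) or
    (condition, variant) -> fraction, and must cover the full variant space.
    Deterministic given ``seed``.
    """
    conditions = tuple(conditions or design.conditions)
    variants = enumerate_variants(design)
    rng = np.random.default_rng(seed)
    true_f: dict[tuple[str, str], float] = {}
    if isinstance(distribution, Mapping):
        for cond in conditions:
            for v in variants:
                if (cond, v) in distribution:
                    f = distribution[(cond, v)]
                elif v in distribution:
                    f = distribution[v]
                else:
                    raise ValueError(
                        f"explicit truth table missing variant {v!r} "
                        f"(condition {cond!r})"
                    )
                if not 0 <= f <= 1:
                    raise ValueError(f"true fraction {f} outside [0, 1]")
                true_f[(cond, v)] = float(f)
    else:
        if distribution == "uniform":
            draw = lambda n: rng.uniform(0.0, 1.0, size=n)
        elif isinstance(distribution, tuple) and distribution[0] == "beta":
            _, a, b = distribution
            draw = lambda n: rng.beta(a, b, size=n)
        else:
            raise ValueError(f"unknown truth distribution {distribution!r}")
        for cond in conditions:
            values = draw(len(variants))
            for v, f in zip(variants, values):
                true_f[(cond, v)] = float(f)
    return TruthManifest(design_name=design.name, true_f=true_f, seed=seed)


def simulate_counts(truth: TruthManifest, params: SimParams) -> pd.DataFrame:
    """Draw per-variant (cleaved, uncleaved) counts from the truth manifest.

    Depth per (condition, variant) follows the depth model; the cleaved count
    is Binomial(depth, true_f).  Returns a DataFrame with columns condition,
    variant, true_f, depth, cleaved, uncleaved.  Deterministic given
    ``params.seed``.
    """
    rng = np.random.default_rng([params.seed, 0xC0])
    keys = sorted(truth.true_f)
    fs = np.array([truth.true_f[k] for k in keys])
    if params.depth_model == "fixed":
        depths = np.full(len(keys), int(round(params.depth)), dtype=np.int64)
    else:
        depths = rng.poisson(params.depth, size=len(keys))
    cleaved = rng.binomial(depths, fs)
    return pd.DataFrame(
        {
            "condition": [k[0] for k in keys],
            "variant": [k[1] for k in keys],
            "true_f": fs,
            "depth": depths,
            "cleaved": cleaved,
            "uncleaved": depths - cleaved,
        }
    )


def _apply_errors(reads: list[str], error_rate: float, rng: np.random.Generator) -> list[str]:
    """iid substitutions at the given rate, uniform over the 3 other bases."""
    if error_rate <= 0:
        return reads
    out = []
    for read in reads:
        arr = np.frombuffer(read.encode("ascii"), dtype=np.uint8)
        n_err = rng.binomial(len(arr), error_rate)
        if n_err == 0:
            out.append(read)
            continue
        arr = arr.copy()
        positions = rng.choice(len(arr), size=n_err, replace=False)
        for p in positions:
            choices = _DNA[_DNA != arr[p]]
            arr[p] = rng.choice(choices)
        out.append(arr.tobytes().decode("ascii"))
    return out


def emit_fastq(
    design: LibraryDesign,
    counts: pd.DataFrame,
    params: SimParams,
    fastq_path,
    manifest_path=None,
) -> int:
    """Write one read per counted molecule to FASTQ; returns reads written.

    Reads are built with :func:`~cleaveseq.designs.build_amplicon`, mutated
    at the substitution rate, truncated to ``read_length`` from the
    adapter_t end, and written in an order shuffled deterministically by the
    seed (so the classifier cannot exploit grouping).  Qualities are
    constant placeholders.  If ``manifest_path`` is given, a TSV manifest of
    the counts plus all parameters is written alongside.
    """
    rng = np.random.default_rng([params.seed, 0xF0])
    reads: list[str] = []
    for row in counts.itertuples(index=False):
        for status, n in ((Status.CLEAVED, row.cleaved), (Status.UNCLEAVED, row.uncleaved)):
            if n <= 0:
                continue
            amplicon = build_amplicon(design, row.variant, status, row.condition)
            reads.extend([amplicon] * int(n))
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    reads = _apply_errors(reads, params.error_rate, rng)
    if params.read_length is not None:
        reads = [r[: params.read_length] for r in reads]

    path = str(fastq_path)
    handle = gzip.open(path, "wt") if path.endswith(".gz") else open(path, "w")
    with handle:
        for i, seq in enumerate(reads):
            handle.write(f"@sim_{i}\n{seq}\n+\n{_PLACEHOLDER_QUALITY * len(seq)}\n")

    if manifest_path is not None:
        manifest = counts.copy()
        manifest.insert(0, "library", design.name)
        manifest["seed"] = params.seed
        manifest["error_rate"] = params.error_rate
        manifest["depth_model"] = params.depth_model
        manifest["read_length"] = (
            "full" if params.read_length is None else params.read_length
        )
        manifest.to_csv(manifest_path, sep="\t", index=False)
    return len(reads)


def simulate_library(
    design: LibraryDesign,
    params: SimParams,
    fastq_path,
    distribution="uniform",
    manifest_path=None,
    conditions: Sequence[str] | None = None,
) -> tuple[TruthManifest, pd.DataFrame, int]:
    """Convenience wrapper: draw truth, draw counts, emit FASTQ.

    Returns (truth manifest, drawn counts, number of reads written).
    """
    truth = draw_truth(design, distribution, seed=params.seed, conditions=conditions)
    counts = simulate_counts(truth, params)
    n = emit_fastq(design, counts, params, fastq_path, manifest_path=manifest_path)
    return truth, counts, n
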