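"""Classification of sequencing reads into (condition, library, variant, status).

Reads are single-end amplicon sequences.  Each read is anchored at the
adapter_t end, demultiplexed by the fixed-offset barcode window, assigned to
a library by comparing its constant (non-degenerate) positions against each
registered design, and finally called cleaved or uncleaved by comparing
against the two per-design references with the degenerate positions
wildcarded.  Matching is substitution-only (no indel alignment): short-read
substitution errors dominate, and reads with indels simply fail the mismatch
threshold.

Because the extra 5' leader of an uncleaved molecule appears *after* the
variable window on the sequenced strand, the variant letters sit at the same
read offsets for both statuses; the diagnostic signal is whether the bases
past the junction look like the reverse-complemented leader (uncleaved) or
the 3' adapter (cleaved).  A read must cover at least ``min_margin`` of the
positions at which the two references differ, otherwise it is rejected as
``too_short``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .designs import LibraryDesign, Status, reverse_complement_dna

UNASSIGNED = "unassigned"

#: Enumerated reject reasons carried on every ReadCall.
REJECT_REASONS = (
    "none",
    "bad_barcode",
    "no_library",
    "too_short",
    "bad_variant",
    "ref_mismatch",
    "ambiguous_status",
)

_COMPLEMENT_TO_RNA = {"A": "U", "C": "G", "G": "C", "T": "A"}

FORWARD = "forward"
REVERSE_COMPLEMENT = "reverse_complement"


@dataclass(slots=True)
class ClassifierParams:
    """Thresholds and read-model options for the classifier.

    max_bc_mismatch:
        Mismatches tolerated in the barcode window (default 0: exact).
    max_ref_mismatch:
        Mismatches tolerated at constant positions against the winning
        reference (default 3).
    min_margin:
        Required lead, in constant-position mismatches, of the winning
        hypothesis over the runner-up (status call and library assignment);
        must be >= 1.
    orientation:
        ``forward`` if reads are on the amplicon top strand (adapter_t
        first), ``reverse_complement`` if the run sequenced the other strand.
    read_length:
        If set, reads are truncated to this many bases from the adapter_t
        end before classification (emulating a fixed-cycle run).
    """

    max_bc_mismatch: int = 0
    max_ref_mismatch: int = 3
    min_margin: int = 1
    orientation: str = FORWARD
    read_length: int | None = None

    def __post_init__(self):
        if self.max_bc_mismatch < 0 or self.max_ref_mismatch < 0:
            raise ValueError("mismatch thresholds must be nonnegative")
        if self.min_margin < 1:
            raise ValueError("min_margin must be >= 1")
        if self.orientation not in (FORWARD, REVERSE_COMPLEMENT):
            raise ValueError(f"unknown orientation {self.orientation!r}")


@dataclass(slots=True)
class ReadCall:
    """Per-read assignment of condition, library, variant and status."""

    read_id: str
    condition: str = UNASSIGNED
    library: str = UNASSIGNED
    status: Status = Status.UNASSIGNED
    variant: str | None = None
    mismatches: int = 0
    reject_reason: str = "none"

    @property
    def assigned(self) -> bool:
        return self.status in (Status.CLEAVED, Status.UNCLEAVED)


class _ReferenceModel:
    """Precomputed per-design reference arrays for fast masked comparison."""

    def __init__(self, design: LibraryDesign):
        self.design = design
        a, b = len(design.adapter_t), design.barcode_length
        self.bc_offset = a
        self.bc_length = b
        L = design.uncleaved_length()
        site = design.cleavage_site

        refs = {}
        for status, frag_start in ((Status.CLEAVED, site), (Status.UNCLEAVED, 0)):
            fragment = design.rna[frag_start:]
            insert = reverse_complement_dna(fragment.replace("U", "T"))
            ref = design.adapter_t + "N" * b + insert + design.adapter_b
            arr = np.frombuffer(ref.encode("ascii"), dtype=np.uint8).copy()
            mask = arr != ord("N")  # constant positions: not barcode, not variant
            refs[status] = (arr, mask)
        self.refs = refs

        # Read offset of RNA position i is a + b + L - 1 - i for both statuses
        # (the uncleaved leader extends the 3' end of the insert only).
        self.variant_offsets = tuple(
            a + b + L - 1 - i for i in design.degenerate_positions
        )
        c_arr = refs[Status.CLEAVED][0]
        u_arr = refs[Status.UNCLEAVED][0]
        n = min(len(c_arr), len(u_arr))
        self.diagnostic_positions = np.flatnonzero(c_arr[:n] != u_arr[:n])
        self.min_variant_span = max(self.variant_offsets, default=a + b)
        self.amplicon_lengths = {s: len(arr) for s, (arr, _) in refs.items()}

    def mismatches(self, read_arr: np.ndarray, status: Status) -> int:
        ref, mask = self.refs[status]
        n = min(len(read_arr), len(ref))
        return int(np.count_nonzero((read_arr[:n] != ref[:n]) & mask[:n]))

    def diagnostic_coverage(self, read_len: int) -> int:
        return int(np.searchsorted(self.diagnostic_positions, read_len))

    def spans_variant(self, read_len: int) -> bool:
        return read_len > self.min_variant_span


def _model_cache(designs: Sequence[LibraryDesign]) -> list[_ReferenceModel]:
    return [_ReferenceModel(d) for d in designs]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _prepare_read(read: str, params: ClassifierParams) -> str:
    read = read.upper()
    if params.orientation == REVERSE_COMPLEMENT:
        read = reverse_complement_dna(read)
    if params.read_length is not None:
        read = read[: params.read_length]
    return read


def demultiplex(
    read: str,
    barcode_map,
    params: ClassifierParams | None = None,
    bc_offset: int | None = None,
) -> tuple[str | None, str]:
    """Assign a read to a condition by its barcode window.

    Returns ``(condition, "none")`` on success, else ``(None, reason)`` with
    reason ``too_short`` or ``bad_barcode``.  The winner must be within
    ``max_bc_mismatch`` of the window and strictly closer than every other
    barcode (ties are rejected).
    """
    params = params or ClassifierParams()
    read = _prepare_read(read, params)
    lengths = {len(b) for b in barcode_map.values()}
    if len(lengths) != 1:
        raise ValueError("barcodes must all have the same length")
    bl = lengths.pop()
    # Barcode sits at a fixed offset after adapter_t; callers that pass bare
    # inserts can give bc_offset=0.
    if bc_offset is None:
        bc_offset = 0
    window = read[bc_offset : bc_offset + bl]
    if len(window) < bl:
        return None, "too_short"
    dists = sorted((_hamming(window, bc), cond) for cond, bc in barcode_map.items())
    best_d, best_cond = dists[0]
    if best_d > params.max_bc_mismatch:
        return None, "bad_barcode"
    if len(dists) > 1 and dists[1][0] - best_d < 1:
        return None, "bad_barcode"
    return best_cond, "none"


def _score_models(
    read_arr: np.ndarray, models: Sequence[_ReferenceModel], params: ClassifierParams
):
    """Per-model (best_mm, mm_cleaved, mm_uncleaved, diag_cov); None if unusable."""
    out = []
    n = len(read_arr)
    for m in models:
        if not m.spans_variant(n):
            out.append(None)
            continue
        mm_c = m.mismatches(read_arr, Status.CLEAVED)
        mm_u = m.mismatches(read_arr, Status.UNCLEAVED)
        out.append((min(mm_c, mm_u), mm_c, mm_u, m.diagnostic_coverage(n)))
    return out


def assign_library(
    read: str,
    designs: Sequence[LibraryDesign],
    params: ClassifierParams | None = None,
) -> tuple[LibraryDesign | None, str]:
    """Pick the registered design whose constant regions best match the read.

    The winner needs mismatches <= ``max_ref_mismatch`` and a lead of at
    least ``min_margin`` over the runner-up design; otherwise
    ``(None, "no_library")`` (or ``too_short`` if no design's variable window
    is covered).
    """
    if not designs:
        raise ValueError("at least one design must be registered")
    params = params or ClassifierParams()
    read_arr = np.frombuffer(
        _prepare_read(read, params).encode("ascii"), dtype=np.uint8
    )
    models = _model_cache(designs)
    scores = _score_models(read_arr, models, params)
    return _pick_library(models, scores, params)


def _pick_library(models, scores, params):
    ranked = sorted(
        (s[0], i) for i, s in enumerate(scores) if s is not None
    )
    if not ranked:
        return None, "too_short"
    best_mm, best_i = ranked[0]
    if best_mm > params.max_ref_mismatch:
        return None, "no_library"
    if len(ranked) > 1 and ranked[1][0] - best_mm < params.min_margin:
        return None, "no_library"
    return models[best_i].design, "none"


def _call_status(
    read: str,
    read_arr: np.ndarray,
    model: _ReferenceModel,
    score,
    params: ClassifierParams,
    call: ReadCall,
) -> ReadCall:
    """Fill status/variant on an already library-assigned call."""
    if score is None or score[3] < params.min_margin:
        call.status = Status.UNASSIGNED
        call.reject_reason = "too_short"
        return call
    _, mm_c, mm_u, _ = score
    best, other = (mm_c, mm_u) if mm_c <= mm_u else (mm_u, mm_c)
    if best > params.max_ref_mismatch:
        call.status = Status.UNASSIGNED
        call.reject_reason = "ref_mismatch"
        call.mismatches = best
        return call
    if other - best < params.min_margin:
        call.status = Status.AMBIGUOUS
        call.reject_reason = "ambiguous_status"
        call.mismatches = best
        return call
    status = Status.CLEAVED if mm_c < mm_u else Status.UNCLEAVED
    letters = []
    for off in model.variant_offsets:
        base = _COMPLEMENT_TO_RNA.get(read[off])
        if base is None:
            call.status = Status.UNASSIGNED
            call.reject_reason = "bad_variant"
            call.mismatches = best
            return call
        letters.append(base)
    call.status = status
    call.variant = "".join(letters)
    call.mismatches = best
    return call


def classify_read(
    read: str,
    design: LibraryDesign,
    params: ClassifierParams | None = None,
    read_id: str = "",
) -> ReadCall:
    """Call cleavage status and variant for a read already assigned to a design.

    Compares the read against the design's cleaved and uncleaved references
    (degenerate positions wildcarded); the winning status needs <=
    ``max_ref_mismatch`` constant-position mismatches and a margin of >=
    ``min_margin`` over the other status, else the call is AMBIGUOUS /
    rejected.  The variant is read back in RNA sense (5'->3', letters ACGU).
    """
    params = params or ClassifierParams()
    read = _prepare_read(read, params)
    model = _ReferenceModel(design)
    read_arr = np.frombuffer(read.encode("ascii"), dtype=np.uint8)
    call = ReadCall(read_id=read_id, library=design.name)
    score = _score_models(read_arr, [model], params)[0]
    return _call_status(read, read_arr, model, score, params, call)


@dataclass
class Tally:
    """Running totals over a classified read stream."""

    total: int = 0
    assigned: int = 0
    rejects: Counter = field(default_factory=Counter)

    def update(self, call: ReadCall) -> None:
        self.total += 1
        if call.assigned:
            self.assigned += 1
        else:
            self.rejects[call.reject_reason] += 1

    def as_dict(self) -> dict:
        d = {"total": self.total, "assigned": self.assigned}
        for reason in REJECT_REASONS[1:]:
            d[reason] = self.rejects.get(reason, 0)
        return d


def classify_records(
    records: Iterable[tuple[str, str]],
    designs: Sequence[LibraryDesign],
    params: ClassifierParams | None = None,
    tally: Tally | None = None,
) -> Iterator[ReadCall]:
    """Classify an iterable of (read_id, sequence) pairs.

    Pipeline per read: demultiplex -> assign library -> call status/variant.
    Reference mismatch scores are computed once and shared between the
    library-assignment and status steps.
    """
    if not designs:
        raise ValueError("at least one design must be registered")
    params = params or ClassifierParams()
    models = _model_cache(designs)
    barcode_map = designs[0].barcode_map
    for d in designs[1:]:
        if dict(d.barcode_map) != dict(barcode_map):
            raise ValueError("all registered designs must share one barcode map")
    bc_offset = len(designs[0].adapter_t)

    for read_id, seq in records:
        read = _prepare_read(seq, params)
        call = ReadCall(read_id=read_id)
        condition, reason = demultiplex(
            read, barcode_map, ClassifierParams(max_bc_mismatch=params.max_bc_mismatch), bc_offset
        )
        if condition is None:
            call.reject_reason = reason
        else:
            call.condition = condition
            read_arr = np.frombuffer(read.encode("ascii"), dtype=np.uint8)
            scores = _score_models(read_arr, models, params)
            design, reason = _pick_library(models, scores, params)
            if design is None:
                call.reject_reason = reason
            else:
                call.library = design.name
                i = next(j for j, m in enumerate(models) if m.design is design)
                _call_status(read, read_arr, models[i], scores[i], params, call)
        if tally is not None:
            tally.update(call)
        yield call


def open_fastq(path):
    """Open a FASTQ file, transparently handling gzip, yielding (id, seq)."""
    import gzip

    path = str(path)
    handle = gzip.open(path, "rt") if path.endswith(".gz") else open(path)
    return handle


def read_fastq(path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a plain or gzipped FASTQ file.

    A malformed record raises ValueError naming the index at which parsing
    failed.
    """
    index = 0
    with open_fastq(path) as handle:
        it = FastqGeneralIterator(handle)
        while True:
            try:
                title, seq, _qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(
                    f"malformed FASTQ record at index {index} in {path}: {exc}"
                ) from exc
            yield title.split()[0], seq
            index += 1


def process_fastq(
    path,
    designs: Sequence[LibraryDesign],
    params: ClassifierParams | None = None,
    tally: Tally | None = None,
) -> Iterator[ReadCall]:
    """Stream a FASTQ file through the full classifier.

    Yields one :class:`ReadCall` per input record; if ``tally`` is given it
    is updated in place so that after exhaustion ``tally.total`` equals the
    number of input records and every reject reason is counted.
    """
    return classify_records(read_fastq(path), designs, params=params, tally=tally)


def write_calls_tsv(calls: Iterable[ReadCall], path) -> int:
    """Write per-read calls as TSV; returns the number of rows written."""
    n = 0
    with open(path, "w") as fh:
        fh.write("read_id\tcondition\tlibrary\tstatus\tvariant\tmismatches\treject_reason\n")
        for c in calls:
            fh.write(
                f"{c.read_id}\t{c.condition}\t{c.library}\t{c.status.value}\t"
                f"{c.variant or ''}\t{c.mismatches}\t{c.reject_reason}\n"
            )
            n += 1
    return n
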