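"""Ribozyme library designs and the in-silico amplicon model.

A self-cleaving ribozyme library is transcribed by T7 RNA polymerase from a
partially randomized DNA template.  Each transcript either cleaves itself at a
fixed site (releasing the 5' leader and leaving the 3' fragment) or stays
intact.  Sequencing converts every molecule into an amplicon of the form

    adapter_t + barcode + reverse-complement(RNA fragment, as DNA) + adapter_b

where the barcode (delivered by the reverse-transcription primer) encodes the
reaction condition, the variable window encodes the variant of the randomized
bases, and the presence or absence of the sequence derived from the 5' leader
distinguishes uncleaved from cleaved molecules.

This module parses and validates library designs, performs in-silico run-off
transcription, enumerates the 4**k variant space, and builds the per-variant
cleaved/uncleaved RNA fragments and canonical amplicons that the classifier
and the simulator both work from.

Coordinates are 0-based and half-open throughout.  ``cleavage_site`` is the
index of the first RNA base retained in the cleaved 3' fragment; all
degenerate positions must lie at or downstream of it (the assay cannot read
randomized bases that are lost with the 5' leader).
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import yaml
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Canonical 17-nt T7 promoter; transcription starts at the base that follows it.
DEFAULT_T7_PROMOTER = "TAATACGACTCACTATA"

DNA_ALPHABET = frozenset("ACGTN")
RNA_ALPHABET = frozenset("ACGUN")
RNA_BASES = "ACGU"


class DesignError(ValueError):
    """A library design record violates a structural invariant."""


class Status(str, enum.Enum):
    """Cleavage status of a single RNA molecule / sequencing read."""

    CLEAVED = "cleaved"
    UNCLEAVED = "uncleaved"
    AMBIGUOUS = "ambiguous"
    UNASSIGNED = "unassigned"


def transcribe(dna_template: str, promoter: str = DEFAULT_T7_PROMOTER) -> str:
    """Run-off transcription of a top-strand DNA template.

    Returns the template substring that starts immediately after the single
    promoter occurrence, with T replaced by U (N is preserved).  Raises
    :class:`DesignError` if the promoter occurs zero or multiple times.
    """
    dna_template = dna_template.upper()
    n = dna_template.count(promoter)
    if n != 1:
        raise DesignError(
            f"template must contain the promoter exactly once, found {n} occurrence(s)"
        )
    start = dna_template.index(promoter) + len(promoter)
    return dna_template[start:].replace("T", "U")


def reverse_complement_dna(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC letters allowed)."""
    return str(Seq(seq).reverse_complement())


def rna_fragment_to_amplicon_insert(rna_fragment: str) -> str:
    """Top-strand DNA insert for an RNA fragment: reverse complement as DNA.

    The amplicon is modeled on the strand on which the RT primer (adapter_t +
    barcode) comes first, so the RNA fragment appears reverse-complemented.
    N survives as N.
    """
    return reverse_complement_dna(rna_fragment.replace("U", "T"))


@dataclass(frozen=True)
class LibraryDesign:
    """A validated partially randomized ribozyme library.

    Parameters
    ----------
    name:
        Library identifier (e.g. ``Lib-Tw``).
    dna_template:
        Top-strand transcription template over {A,C,G,T,N}; contains the
        promoter exactly once.
    promoter:
        T7 promoter sequence present in the template.
    rna:
        Run-off transcript derived from the template (T -> U, N preserved).
    degenerate_positions:
        0-based RNA indices of the randomized bases, in 5'->3' order.
    cleavage_site:
        0-based RNA index of the first base of the retained 3' fragment.
    barcode_map:
        condition label -> barcode DNA string (equal lengths, pairwise
        distinct).
    adapter_t, adapter_b:
        DNA adapters flanking the final amplicon (barcode side and 3' side).
    """

    name: str
    dna_template: str
    promoter: str
    rna: str
    degenerate_positions: tuple[int, ...]
    cleavage_site: int
    barcode_map: Mapping[str, str]
    adapter_t: str
    adapter_b: str

    @property
    def k(self) -> int:
        """Number of degenerate (randomized) bases."""
        return len(self.degenerate_positions)

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.barcode_map)

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self.barcode_map.values())))

    def uncleaved_length(self) -> int:
        return len(self.rna)

    def cleaved_length(self) -> int:
        return len(self.rna) - self.cleavage_site


@dataclass(frozen=True)
class VariantConstruct:
    """One variant's uncleaved transcript and its cleaved 3' fragment."""

    variant: str
    uncleaved_rna: str
    cleaved_rna: str


def load_library_design(record: Mapping) -> LibraryDesign:
    """Build and validate a :class:`LibraryDesign` from a structured record.

    The record supplies ``name``, ``dna_template``, ``cleavage_site``,
    ``barcodes`` (condition -> sequence), ``adapter_t`` and ``adapter_b``;
    ``promoter`` defaults to the canonical T7 sequence.  The transcript, the
    degenerate positions and k are derived here.
    """
    try:
        name = record["name"]
        dna_template = str(record["dna_template"]).upper()
        cleavage_site = int(record["cleavage_site"])
        barcode_map = dict(record["barcodes"])
        adapter_t = str(record["adapter_t"]).upper()
        adapter_b = str(record["adapter_b"]).upper()
    except KeyError as exc:
        raise DesignError(f"design record is missing required field {exc}") from exc
    promoter = str(record.get("promoter", DEFAULT_T7_PROMOTER)).upper()

    bad = set(dna_template) - DNA_ALPHABET
    if bad:
        raise DesignError(f"template contains non-DNA characters: {sorted(bad)}")
    rna = transcribe(dna_template, promoter)  # validates single promoter
    degenerate_positions = tuple(i for i, b in enumerate(rna) if b == "N")

    if not 0 < cleavage_site < len(rna):
        raise DesignError(
            f"cleavage_site {cleavage_site} outside (0, {len(rna)})"
        )
    upstream = [i for i in degenerate_positions if i < cleavage_site]
    if upstream:
        raise DesignError(
            "degenerate positions upstream of the cleavage site are lost with the "
            f"5' leader and cannot be assayed: {upstream}"
        )

    barcode_map = {str(c): str(b).upper() for c, b in barcode_map.items()}
    if not barcode_map:
        raise DesignError("barcode_map must define at least one condition")
    lengths = {len(b) for b in barcode_map.values()}
    if len(lengths) != 1:
        raise DesignError("barcodes must all have the same length")
    if len(set(barcode_map.values())) != len(barcode_map):
        raise DesignError("barcodes must be pairwise distinct")
    for bc in barcode_map.values():
        if not set(bc) <= set("ACGT"):
            raise DesignError(f"barcode {bc!r} is not plain DNA")
    for label, adapter in (("adapter_t", adapter_t), ("adapter_b", adapter_b)):
        if not adapter or not set(adapter) <= set("ACGT"):
            raise DesignError(f"{label} must be a non-empty plain DNA string")

    return LibraryDesign(
        name=str(name),
        dna_template=dna_template,
        promoter=promoter,
        rna=rna,
        degenerate_positions=degenerate_positions,
        cleavage_site=cleavage_site,
        barcode_map=barcode_map,
        adapter_t=adapter_t,
        adapter_b=adapter_b,
    )


def load_design_yaml(path) -> LibraryDesign:
    """Load a single library design from a YAML file."""
    with open(path) as fh:
        record = yaml.safe_load(fh)
    if not isinstance(record, Mapping):
        raise DesignError(f"{path}: expected a mapping at top level")
    return load_library_design(record)


def enumerate_variants(design_or_k: "LibraryDesign | int") -> list[str]:
    """All 4**k variant strings over {A,C,G,U} in lexicographic order."""
    k = design_or_k.k if isinstance(design_or_k, LibraryDesign) else int(design_or_k)
    if k < 0:
        raise ValueError("k must be nonnegative")
    return ["".join(p) for p in itertools.product(RNA_BASES, repeat=k)]


def realize_variant(design: LibraryDesign, variant: str) -> VariantConstruct:
    """Substitute a variant into the degenerate positions of the design RNA.

    Returns the full-length (uncleaved) transcript and the cleaved 3'
    fragment, i.e. the suffix starting at ``cleavage_site``.
    """
    if len(variant) != design.k:
        raise ValueError(
            f"variant length {len(variant)} != k={design.k} for {design.name}"
        )
    if not set(variant) <= set(RNA_BASES):
        raise ValueError(f"variant {variant!r} is not over {{A,C,G,U}}")
    rna = list(design.rna)
    for pos, base in zip(design.degenerate_positions, variant):
        rna[pos] = base
    uncleaved = "".join(rna)
    return VariantConstruct(
        variant=variant,
        uncleaved_rna=uncleaved,
        cleaved_rna=uncleaved[design.cleavage_site :],
    )


def build_amplicon(
    design: LibraryDesign,
    variant: str,
    status: Status | str,
    condition: str,
) -> str:
    """Canonical top-strand amplicon for one molecule.

    ``adapter_t + barcode(condition) + revcomp(fragment as DNA) + adapter_b``
    with fragment = the uncleaved transcript or the cleaved 3' fragment.  The
    uncleaved amplicon is exactly ``cleavage_site`` bases longer than the
    cleaved amplicon of the same variant; the extra bases (the
    reverse-complemented 5' leader) sit between the variable window and
    adapter_b and are what the classifier uses to call status.
    """
    status = Status(status)
    if status not in (Status.CLEAVED, Status.UNCLEAVED):
        raise ValueError(f"cannot build an amplicon for status {status.value!r}")
    try:
        barcode = design.barcode_map[condition]
    except KeyError:
        raise KeyError(
            f"unknown condition {condition!r} for {design.name}; "
            f"known: {list(design.barcode_map)}"
        ) from None
    construct = realize_variant(design, variant)
    fragment = (
        construct.cleaved_rna if status is Status.CLEAVED else construct.uncleaved_rna
    )
    return (
        design.adapter_t
        + barcode
        + rna_fragment_to_amplicon_insert(fragment)
        + design.adapter_b
    )


def export_variant_fasta(design: LibraryDesign, path, statuses=(Status.UNCLEAVED, Status.CLEAVED)) -> int:
    """Write per-variant reference RNA fragments as FASTA; returns record count."""
    from Bio import SeqIO

    records = []
    for variant in enumerate_variants(design):
        construct = realize_variant(design, variant)
        for status in (Status(s) for s in statuses):
            seq = (
                construct.cleaved_rna
                if status is Status.CLEAVED
                else construct.uncleaved_rna
            )
            records.append(
                SeqRecord(
                    Seq(seq),
                    id=f"{design.name}|{variant}|{status.value}",
                    description="",
                )
            )
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    return len(records)


# ---------------------------------------------------------------------------
# Shipped fixture designs
# ---------------------------------------------------------------------------
# Templates are the published top-strand sequences of the three libraries:
# a twister ribozyme with five randomized bases at/next to its T1 pseudoknot
# (Lib-Tw) and two guanine-aptazyme libraries built on the HDV-like ribozyme
# drz-Agam-2-1, with the aptamer joined through four randomized bases at the
# J1/2 loop (Lib-J1/2) or in place of the P4 stem (Lib-P4).
#
# Barcodes and adapters below are SYNTHETIC stand-ins (the real RT-primer /
# adapter oligos are not part of the published templates): two
# Illumina-index-style 6-mers for the -guanine / +guanine conditions and
# TruSeq-style flanking adapters.  Cleavage sites are approximate
# reconstructions — the published account marks them only graphically — and
# are chosen as a short 5' leader upstream of all randomized bases, which is
# the only property the pipeline depends on.

_SYNTHETIC_BARCODES = {"minus": "ATCACG", "plus": "CGATGT"}
_SYNTHETIC_ADAPTER_T = "ACACGACGCTCTTCCGATCT"
_SYNTHETIC_ADAPTER_B = "AGATCGGAAGAGCACACGTC"

_FIXTURE_RECORDS = (
    {
        "name": "Lib-Tw",
        "dna_template": (
            "TAATACGACTCACTATA"
            "GGGCGCGGCATTAATGCAGCTTTATTGGAAACAATAAAGCG"
            "NNNNN"
            "AAGCCCGCAAAAATAGCAGAGTAATGTCGCG"
        ),
        "cleavage_site": 9,  # approximate; within the 5' P1 region
        "barcodes": _SYNTHETIC_BARCODES,
        "adapter_t": _SYNTHETIC_ADAPTER_T,
        "adapter_b": _SYNTHETIC_ADAPTER_B,
    },
    {
        "name": "Lib-J1/2",
        "dna_template": (
            "TAATACGACTCACTATA"
            "GGGCCGCGACTCTAGAAGTGATGCTCTGC"
            "NNNN"
            "ATAATCGCGTGGATATGGCACGCAAGTTTCTACCGGGCACCGTAAATGTCCGACTACTCC"
            "TATTCCGGCACGTCCACGTCGTGCAGAGCGGTAACATGCGTTACTAGGGGTGCAAGAGCT"
            "CTTTTTGAGGAGGAGCTCTTTTTGCTGCACTAGTTGCATCAGATGGTAACGCATGGCTAA"
            "GCCGGAAAGGGGGAGAC"
        ),
        "cleavage_site": 10,  # approximate; HDV-like ribozymes cleave just 5' of the core
        "barcodes": _SYNTHETIC_BARCODES,
        "adapter_t": _SYNTHETIC_ADAPTER_T,
        "adapter_b": _SYNTHETIC_ADAPTER_B,
    },
    {
        "name": "Lib-P4",
        "dna_template": (
            "TAATACGACTCACTATA"
            "GGGCCGCGACTCTAGAAGTGATGCTCTGCAAATGGGGTAGGAGGCGATGCCTCGTCCTC"
            "ATACCCAACTCCTATTCCGGCACGTCCACGTCGTGCAGAGCGGTA"
            "NNNN"
            "TATAATCGCGTGGATATGGCACGCAAGTTTCTACCGGGCACCGTAAATGTCCGACTAGTA"
            "GCTAAGCCGGAAAGGGGGAGAC"
        ),
        "cleavage_site": 10,  # approximate; see Lib-J1/2
        "barcodes": _SYNTHETIC_BARCODES,
        "adapter_t": _SYNTHETIC_ADAPTER_T,
        "adapter_b": _SYNTHETIC_ADAPTER_B,
    },
)


def builtin_designs() -> dict[str, LibraryDesign]:
    """The three shipped fixture designs, keyed by name."""
    return {rec["name"]: load_library_design(rec) for rec in _FIXTURE_RECORDS}
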