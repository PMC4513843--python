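"""End-to-end orchestration: classify -> tabulate -> profile -> gate -> report.

Runs are driven by a :class:`RunConfig` (loadable from YAML); every run
writes a machine-readable parameter record (``run.json``) sufficient to
reproduce it, and one structured log line per stage with read counts in and
out.  Stage failures abort with a stage-labeled message.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .activity import (
    CountTable,
    FitResult,
    GateCriteria,
    build_profile,
    compare_profiles,
    tabulate,
    write_counts_tsv,
    write_profile_tsv,
    write_tally_tsv,
)
from .classify import ClassifierParams, Tally, process_fastq, write_calls_tsv
from .designs import LibraryDesign, builtin_designs, load_design_yaml

logger = logging.getLogger("cleaveseq")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration for one end-to-end run.

    ``designs`` entries are YAML file paths or ``builtin:<name>`` references
    to the shipped fixture designs.  ``condition_minus``/``condition_plus``
    name the two barcoded conditions used for the on/off analysis.
    """

    fastq: list[str]
    designs: list[str]
    out_dir: str
    condition_minus: str = "minus"
    condition_plus: str = "plus"
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    gate: GateCriteria = field(default_factory=GateCriteria)
    min_depth: int = 50
    write_calls: bool = True
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        classifier = ClassifierParams(**raw.pop("classifier", {}))
        gate = GateCriteria(**raw.pop("gate", {}))
        return cls(classifier=classifier, gate=gate, **raw)


def resolve_designs(entries: Sequence[str]) -> list[LibraryDesign]:
    """Resolve ``builtin:<name>`` references and YAML paths to designs."""
    shipped = builtin_designs()
    out = []
    for entry in entries:
        if entry.startswith("builtin:"):
            name = entry.split(":", 1)[1]
            try:
                out.append(shipped[name])
            except KeyError:
                raise PipelineError(
                    f"[config] unknown builtin design {name!r}; "
                    f"available: {list(shipped)}"
                ) from None
        else:
            if not Path(entry).exists():
                raise PipelineError(f"[config] design file not found: {entry}")
            out.append(load_design_yaml(entry))
    if not out:
        raise PipelineError("[config] no designs configured")
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns a dict of output paths and stats."""
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    designs = resolve_designs(config.designs)
    for path in config.fastq:
        if not Path(path).exists():
            raise PipelineError(f"[config] FASTQ not found: {path}")
    logger.info("config: %d design(s), %d FASTQ file(s)", len(designs), len(config.fastq))

    paths = {
        "calls": out_dir / "calls.tsv",
        "counts": out_dir / "counts.tsv",
        "profile": out_dir / "profile.tsv",
        "gate": out_dir / "gate.tsv",
        "tally": out_dir / "tally.tsv",
        "run": out_dir / "run.json",
    }

    tally = Tally()
    try:
        calls_fh = open(paths["calls"], "w") if config.write_calls else None
        if calls_fh:
            calls_fh.write(
                "read_id\tcondition\tlibrary\tstatus\tvariant\tmismatches\treject_reason\n"
            )

        def stream():
            for fq in config.fastq:
                for call in process_fastq(fq, designs, config.classifier, tally):
                    if calls_fh:
                        calls_fh.write(
                            f"{call.read_id}\t{call.condition}\t{call.library}\t"
                            f"{call.status.value}\t{call.variant or ''}\t"
                            f"{call.mismatches}\t{call.reject_reason}\n"
                        )
                    yield call

        try:
            table = tabulate(stream(), designs)
        finally:
            if calls_fh:
                calls_fh.close()
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"[classify] {exc}") from exc
    logger.info(
        "classify: %d reads in, %d assigned, %d rejected",
        tally.total,
        tally.assigned,
        tally.total - tally.assigned,
    )

    try:
        write_counts_tsv(table, paths["counts"])
        write_tally_tsv(tally, paths["tally"])
        profile = build_profile(
            table,
            condition_minus=config.condition_minus,
            condition_plus=config.condition_plus,
            criteria=config.gate,
            min_depth=config.min_depth,
        )
        write_profile_tsv(profile, paths["profile"])
        gate_table = profile[profile["gate"]].reset_index(drop=True)
        write_profile_tsv(gate_table, paths["gate"])
    except Exception as exc:
        raise PipelineError(f"[quantify] {exc}") from exc
    logger.info(
        "quantify: %d variant profiles, %d pass the gate", len(profile), len(gate_table)
    )

    record = {
        "cleaveseq_version": __version__,
        "config": {
            **{
                k: v
                for k, v in dataclasses.asdict(config).items()
                if k not in ("classifier", "gate")
            },
            "classifier": dataclasses.asdict(config.classifier),
            "gate": dataclasses.asdict(config.gate),
        },
        "designs": [
            {"name": d.name, "k": d.k, "rna_length": len(d.rna), "cleavage_site": d.cleavage_site}
            for d in designs
        ],
        "tally": tally.as_dict(),
        "gate_passes": int(len(gate_table)),
    }
    with open(paths["run"], "w") as fh:
        json.dump(record, fh, indent=2)

    return {
        "paths": {k: str(v) for k, v in paths.items()},
        "tally": tally.as_dict(),
        "table": table,
        "profile": profile,
        "gate_table": gate_table,
    }


def sequencing_capacity(total_reads: int, mean_depth: float) -> tuple[int, int]:
    """Assayable library size at a sequencing budget.

    Returns ``(variants, equivalent_random_bases)`` where variants is
    floor(total_reads / mean_depth) and the equivalent number of fully
    randomized bases is round(log4(variants)).  E.g. 2e9 reads at 500 reads
    per variant supports 4e6 variants, about 11 randomized bases.
    """
    if total_reads <= 0 or mean_depth <= 0:
        raise ValueError("total_reads and mean_depth must be positive")
    variants = int(total_reads // mean_depth)
    if variants < 1:
        raise ValueError("budget supports no variant at the requested depth")
    return variants, round(math.log(variants, 4))


def make_report(
    profile: pd.DataFrame,
    out_dir,
    comparisons: Mapping[str, pd.DataFrame] | None = None,
    top_k: int = 10,
) -> dict:
    """Derived analyses from an activity profile.

    Writes phenotype scatter data (f_minus vs f_plus with the gate flag),
    top-k tables per condition, and — for each supplied orthogonal
    measurement table (columns ``variant``, ``fraction``) — paired scatter
    data plus an OLS :class:`FitResult` against the profile's f_plus (or
    f_minus if f_plus is absent).  Comparison variants missing from the
    profile are listed and skipped with a warning.  Returns the fit results
    and written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}

    scatter = profile[["library", "variant", "f_minus", "f_plus", "gate"]]
    scatter_path = out_dir / "phenotype_scatter.tsv"
    scatter.to_csv(scatter_path, sep="\t", index=False)
    written["phenotype_scatter"] = str(scatter_path)

    for cond in ("minus", "plus"):
        col = f"f_{cond}"
        top = (
            profile.sort_values([col, "variant"], ascending=[False, True])
            .head(top_k)[["library", "variant", col, "ratio", "gate"]]
        )
        path = out_dir / f"top_{cond}.tsv"
        top.to_csv(path, sep="\t", index=False)
        written[f"top_{cond}"] = str(path)

    fits: dict[str, FitResult] = {}
    skipped: dict[str, list[str]] = {}
    for name, table in (comparisons or {}).items():
        merged = profile.merge(table, on="variant", how="right", indicator=True)
        missing = merged.loc[merged["_merge"] == "right_only", "variant"].tolist()
        if missing:
            logger.warning(
                "report: comparison %r has %d variant(s) absent from the profile, "
                "skipped: %s",
                name,
                len(missing),
                missing,
            )
            skipped[name] = missing
        paired = merged[merged["_merge"] == "both"]
        ref_col = "f_plus" if paired["f_plus"].notna().any() else "f_minus"
        path = out_dir / f"comparison_{name}.tsv"
        paired[["variant", ref_col, "fraction"]].to_csv(path, sep="\t", index=False)
        written[f"comparison_{name}"] = str(path)
        if len(paired) >= 3:
            fits[name] = compare_profiles(
                paired[ref_col].to_numpy(), paired["fraction"].to_numpy()
            )

    return {"paths": written, "fits": fits, "skipped": skipped}
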