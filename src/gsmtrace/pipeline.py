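"""Config-driven pipeline orchestration with a replayable run log.

A reconstruction is described as an ordered list of steps in a YAML file;
each step names a registered operation (reading a draft, merging an
orthology-derived model, identifier mapping, gap-filling, curation,
exports, reports) with its input paths and the provenance stamp
(category/tool/source) to apply. External reconstruction tools are *not*
invoked — the pipeline consumes their SBML/TSV outputs as declared step
inputs, which keeps a run self-contained and reproducible from its inputs.

Every executed step appends a :class:`RunRecord` with the operation,
parameters, input file digests and entity-count deltas; re-running the same
config on the same inputs yields an identical final model and identical
deltas (timestamps aside).
"""

from __future__ import annotations

import hashlib
import os
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from .curation import CurationLog, apply_form, parse_forms
from .flatfile import read_flat, write_flat
from .mapping import map_identifiers, read_mapping_table
from .matrix import export_matrix
from .model import GsmtraceError, Model, SourceTag, merge_models
from .rdf_export import export_rdf
from .report import pathway_completeness, quality_report
from .sbml_io import read_sbml, write_sbml
from .topology import (
    compute_scope,
    gapfill,
    instantiate_class_reactions,
    read_compound_list,
    unproducible_targets,
)
from .wiki import generate_wiki


class ConfigError(GsmtraceError):
    """Invalid pipeline configuration (reported before any step runs)."""


class StepError(GsmtraceError):
    """A pipeline step failed; carries the partial run log for resumption."""

    def __init__(self, step_index: int, message: str, log: "RunLog"):
        self.step_index = step_index
        self.log = log
        super().__init__(f"step {step_index} failed: {message}")


@dataclass
class RunRecord:
    step: int
    operation: str
    parameters: dict
    input_digests: dict[str, str]
    output_digests: dict[str, str]
    deltas: dict[str, int]
    timestamp: str


@dataclass
class RunLog:
    """Append-only record of an executed pipeline."""

    records: list[RunRecord] = field(default_factory=list)

    def to_tsv(self, path: Union[str, os.PathLike]) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as handle:
            handle.write(
                "step\toperation\tparameters\tinput_digests\toutput_digests"
                "\tdeltas\ttimestamp\n"
            )
            for record in self.records:
                handle.write(
                    f"{record.step}\t{record.operation}\t{record.parameters}"
                    f"\t{record.input_digests}\t{record.output_digests}"
                    f"\t{record.deltas}\t{record.timestamp}\n"
                )


@dataclass
class PipelineConfig:
    """Parsed configuration: global settings plus ordered steps."""

    model_id: str = "model"
    ref_db: str = ""
    workspace: Path = Path(".")
    seed: int = 0
    steps: list[dict] = field(default_factory=list)

    @classmethod
    def load(cls, path: Union[str, os.PathLike]) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        workspace = Path(raw.get("workspace", Path(path).parent))
        config = cls(
            model_id=str(raw.get("model_id", "model")),
            ref_db=str(raw.get("ref_db", "")),
            workspace=workspace,
            seed=int(raw.get("seed", 0)),
            steps=list(raw.get("steps", [])),
        )
        config.validate()
        return config

    def validate(self) -> None:
        for index, step in enumerate(self.steps):
            if not isinstance(step, dict) or "op" not in step:
                raise ConfigError(f"step {index} lacks an 'op' field")
            if step["op"] not in OPERATIONS:
                raise ConfigError(
                    f"step {index}: unknown operation {step['op']!r} "
                    f"(known: {', '.join(sorted(OPERATIONS))})"
                )


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _counts(model: Model) -> dict[str, int]:
    counts = model.entity_counts()
    counts["relations"] = len(model.relations)
    counts["tags"] = len(model.tags)
    return counts


# ---------------------------------------------------------------- steps
# Each handler: (model, step dict, config, step index) -> (model, outputs)


def _load_model(path: Path) -> Model:
    if path.suffix.lower() in (".sbml", ".xml"):
        return read_sbml(path)
    return read_flat(path)


def _step_read(model, step, config, index):
    path = config.workspace / step["path"]
    loaded = _load_model(path)
    loaded.meta["model_id"] = config.model_id
    if config.ref_db:
        loaded.meta["ref_db"] = config.ref_db
    category = step.get("category")
    if category:
        merged = merge_models(
            Model(model_id=config.model_id, ref_db=config.ref_db),
            loaded,
            category,
            step.get("tool", ""),
            step.get("source", ""),
            index,
        )
        merged.meta["model_id"] = config.model_id
        return merged, []
    return loaded, []


def _step_merge(model, step, config, index):
    addition = _load_model(config.workspace / step["path"])
    merged = merge_models(
        model,
        addition,
        step.get("category", "orthology"),
        step.get("tool", ""),
        step.get("source", ""),
        index,
    )
    return merged, []


def _step_map(model, step, config, index):
    table = read_mapping_table(config.workspace / step["table"])
    mapped, report = map_identifiers(model, table)
    mapped.meta["model_id"] = model.meta.get("model_id", config.model_id)
    return mapped, []


def _step_instantiate(model, step, config, index):
    extended, _skipped = instantiate_class_reactions(
        model, max_variants=int(step.get("max_variants", 64))
    )
    return extended, []


def _step_gapfill(model, step, config, index):
    database = _load_model(config.workspace / step["database"])
    if step.get("instantiate", False):
        database, _ = instantiate_class_reactions(database)
    seeds = read_compound_list(config.workspace / step["seeds"])
    targets = read_compound_list(config.workspace / step["targets"])
    completions = gapfill(
        model, database, seeds, targets,
        max_size=int(step.get("max_size", 4)),
    )
    if not completions:
        raise GsmtraceError("gap-filling found no completion within max_size")
    chosen = completions[0]
    for rid in sorted(chosen.reactions):
        model.add_entity(database.entities[rid])
        for relation in database.relations_from(rid):
            if relation.object not in model.entities:
                model.add_entity(database.entities[relation.object])
            model.add_relation(relation)
        model.add_tag(SourceTag(
            rid, "gap-filling", step.get("tool", "topological-completion"),
            step.get("source", step["database"]), "", index,
        ))
    return model, []


def _step_curate(model, step, config, index):
    forms = parse_forms(config.workspace / step["forms"])
    log = CurationLog()
    for form in forms:
        apply_form(model, form, log, step=index)
    return model, []


def _step_write(model, step, config, index):
    path = config.workspace / step["path"]
    if step["op"] == "write_sbml":
        write_sbml(model, path, level=int(step.get("level", 3)))
    elif step["op"] == "write_flat":
        write_flat(model, path)
    elif step["op"] == "export_matrix":
        export_matrix(model, path)
    else:
        export_rdf(model, path)
    return model, [path]


def _step_report(model, step, config, index):
    outdir = config.workspace / step.get("out", "reports")
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = []
    quality = quality_report(model)
    quality_path = outdir / "quality.tsv"
    with open(quality_path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write("metric\tvalue\n")
        handle.write(f"gene_association_ratio\t{quality.gene_association_ratio}\n")
        for name, value in quality.counts.items():
            handle.write(f"{name}\t{value}\n")
        handle.write(f"mass_unbalanced\t{len(quality.mass_unbalanced)}\n")
        handle.write(f"charge_unbalanced\t{len(quality.charge_unbalanced)}\n")
        handle.write(f"undetermined\t{len(quality.undetermined)}\n")
    outputs.append(quality_path)
    if step.get("pathways"):
        defs = _load_model(config.workspace / step["pathways"])
        completeness = pathway_completeness(model, defs)
        completeness_path = outdir / "pathway_completeness.tsv"
        completeness.to_tsv(completeness_path)
        outputs.append(completeness_path)
    return model, outputs


def _step_wiki(model, step, config, index):
    outdir = config.workspace / step.get("out", "wiki")
    defs = None
    if step.get("pathways"):
        defs = _load_model(config.workspace / step["pathways"])
    pages = generate_wiki(model, outdir, pathway_defs=defs)
    return model, [outdir / pages[0]]


OPERATIONS = {
    "read_sbml": _step_read,
    "read_flat": _step_read,
    "merge": _step_merge,
    "map_identifiers": _step_map,
    "instantiate_classes": _step_instantiate,
    "gapfill": _step_gapfill,
    "curate": _step_curate,
    "write_sbml": _step_write,
    "write_flat": _step_write,
    "export_matrix": _step_write,
    "export_rdf": _step_write,
    "report": _step_report,
    "wiki": _step_wiki,
}

_INPUT_KEYS = ("path", "database", "seeds", "targets", "forms", "table", "pathways")


def run_pipeline(
    config: Union[PipelineConfig, str, os.PathLike]
) -> tuple[Model, RunLog]:
    """Execute the configured steps in order; returns (final model, log).

    The configuration is validated before any step executes. A failing step
    raises :class:`StepError` carrying the partial log.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.load(config)
    config.validate()
    model = Model(model_id=config.model_id, ref_db=config.ref_db)
    log = RunLog()
    for index, step in enumerate(config.steps):
        before = _counts(model)
        input_digests = {}
        for key in _INPUT_KEYS:
            if key in step and step["op"] not in ("write_sbml", "write_flat",
                                                  "export_matrix", "export_rdf"):
                path = config.workspace / step[key]
                if path.exists():
                    input_digests[step[key]] = _digest(path)
        try:
            model, outputs = OPERATIONS[step["op"]](model, step, config, index)
        except GsmtraceError as exc:
            raise StepError(index, str(exc), log) from exc
        after = _counts(model)
        log.records.append(
            RunRecord(
                step=index,
                operation=step["op"],
                parameters={
                    k: v for k, v in sorted(step.items()) if k != "op"
                },
                input_digests=input_digests,
                output_digests={
                    str(p.name): _digest(Path(p)) for p in outputs if Path(p).is_file()
                },
                deltas={
                    key: after[key] - before.get(key, 0) for key in sorted(after)
                },
                timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
            )
        )
    return model, log


def describe_run(log: RunLog) -> str:
    """Human-readable per-step summary with entity-count deltas and totals."""
    lines = ["step\toperation\tdeltas"]
    totals: dict[str, int] = {}
    for record in log.records:
        changed = {k: v for k, v in record.deltas.items() if v}
        lines.append(f"{record.step}\t{record.operation}\t{changed or '-'}")
        for key, value in record.deltas.items():
            totals[key] = totals.get(key, 0) + value
    lines.append(f"totals\t\t{ {k: v for k, v in sorted(totals.items()) if v} }")
    return "\n".join(lines)
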