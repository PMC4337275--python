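"""End-to-end pipeline: curate -> trim -> tree -> events -> tables -> report.

The pipeline mirrors the analysis workflow: candidate proteins are screened
against the reference anchor, accepted sequences (if an alignment is
supplied) are trimmed to their conserved core, a gene tree is either read
from file (the normal case: trees are inferred upstream) or built with the
neighbor-joining stand-in at fixture scale, duplication and origin events
are called, the LIPOR complement table is classified and associated with
por copy number, and optionally degenerate primers are proposed.  Every
stage writes a TSV next to the summary; a resolved copy of the
configuration is written alongside so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .alignment import Alignment, trim_core
from .curation import ReferenceAnchor, apply_curation
from .events import (
    DEFAULT_DONOR_MAP,
    assign_origins,
    detect_duplications,
    duplication_calls_table,
    origin_calls_table,
)
from .lipor import (
    complement_table,
    parse_complement_table,
    por_lipor_association,
    summarize_by_group,
)
from .primers import build_primer, find_conserved_blocks
from .records import ConfigurationError, InputError, read_fasta
from .trees import (
    nj_build,
    parse_newick,
    read_leaf_metadata,
    root_on_outgroup,
    write_newick,
)
from .alignment import pairwise_distance_matrix

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage-level failure; the message names the failing stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class AnchorSpec:
    reference_fasta: str = ""
    rossman_start: int = 0
    tyr_pos: int = 0
    lys_pos: int = 0
    cys_pos: int = 0


@dataclass
class ScreenParams:
    window: int = 10
    min_length: int = 150
    max_unknown_fraction: float = 0.05
    dedup_identity: float = 0.99


@dataclass
class TrimParams:
    max_gap_fraction: float = 0.0
    max_x_fraction: float = 0.0


@dataclass
class EventParams:
    support_threshold: float = 0.95
    purity_threshold: float = 0.8
    min_context: int = 3
    min_shared: int = 2
    outgroup_lineage: str = "cyanobacteria"
    donor_map: dict = field(default_factory=lambda: dict(DEFAULT_DONOR_MAP))


@dataclass
class PrimerParams:
    window_aa: int = 7
    top_k: int = 3
    max_degeneracy: int = 512
    tail: str = ""


@dataclass
class Stages:
    screen: bool = True
    trim: bool = True
    tree: str = "input"  # "input" | "nj" | "off"
    events: bool = True
    lipor: bool = True
    primers: bool = False


@dataclass
class PipelineConfig:
    """Fully resolved configuration; unknown keys are rejected on load."""

    output_dir: str = "portrace_out"
    sequences: str = ""
    alignment: str = ""
    tree: str = ""
    leaf_metadata: str = ""
    complement_table: str = ""
    anchor: AnchorSpec = field(default_factory=AnchorSpec)
    screen: ScreenParams = field(default_factory=ScreenParams)
    trim: TrimParams = field(default_factory=TrimParams)
    events: EventParams = field(default_factory=EventParams)
    primers: PrimerParams = field(default_factory=PrimerParams)
    stages: Stages = field(default_factory=Stages)
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _build_dataclass(cls, data, path="config")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build_dataclass(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigurationError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        default = fields[name].default_factory() if fields[name].default_factory is not dataclasses.MISSING else fields[name].default  # type: ignore[misc]
        if dataclasses.is_dataclass(default):
            kwargs[name] = _build_dataclass(type(default), value, f"{path}.{name}")
        else:
            kwargs[name] = value
    return cls(**kwargs)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _load_anchor(config: PipelineConfig) -> ReferenceAnchor:
    spec = config.anchor
    if not spec.reference_fasta:
        raise PipelineError("screen", "anchor.reference_fasta is not set")
    refs = read_fasta(spec.reference_fasta)
    if not refs:
        raise PipelineError("screen", "reference FASTA is empty")
    try:
        return ReferenceAnchor(
            refs[0], spec.rossman_start, spec.tyr_pos, spec.lys_pos, spec.cys_pos
        )
    except ConfigurationError as exc:
        raise PipelineError("screen", str(exc)) from exc


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and write per-stage outputs.

    Returns the summary report (also written as ``summary.json``).
    Timestamps are confined to the log so repeated runs on identical input
    produce byte-identical result files.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "portrace.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    root_logger = logging.getLogger("portrace")
    root_logger.addHandler(handler)
    root_logger.setLevel(logging.INFO)

    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
    }
    try:
        with open(out / "resolved_config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
        logger.info(
            "pipeline start: version=%s seed=%s config_hash=%s",
            __version__, config.seed, report["config_hash"],
        )

        accepted_ids: list[str] | None = None
        if config.stages.screen:
            accepted_ids = _stage_screen(config, out, report)
        if config.stages.trim and config.alignment:
            _stage_trim(config, out, report)
        tree = None
        if config.stages.tree != "off":
            tree = _stage_tree(config, out, report)
        if config.stages.events and tree is not None:
            _stage_events(config, tree, out, report)
        if config.stages.lipor and config.complement_table:
            _stage_lipor(config, out, report)
        if config.stages.primers and config.alignment:
            _stage_primers(config, out, report)
    finally:
        root_logger.removeHandler(handler)
        handler.close()

    with open(out / "summary.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _stage_screen(config: PipelineConfig, out: Path, report: dict) -> list[str]:
    if not config.sequences:
        raise PipelineError("screen", "no input sequence FASTA configured")
    try:
        records = read_fasta(config.sequences)
    except (OSError, InputError) as exc:
        raise PipelineError("screen", str(exc)) from exc
    if not records:
        raise PipelineError("screen", "input FASTA contains no sequences")
    anchor = _load_anchor(config)
    p = config.screen
    accepted, rejected = apply_curation(
        records, anchor,
        min_length=p.min_length,
        max_unknown_fraction=p.max_unknown_fraction,
        dedup_identity=p.dedup_identity,
        window=p.window,
    )
    rows = []
    for rep in accepted:
        rows.append(_report_row(rep, "accepted", ""))
    for rej in rejected:
        rows.append(_report_row(rej.report, "rejected", rej.reason))
    frame = pd.DataFrame(rows).sort_values("seq_id").reset_index(drop=True)
    frame.to_csv(out / "screen_report.tsv", sep="\t", index=False)
    report["screen"] = {
        "n_input": len(records),
        "n_accepted": len(accepted),
        "n_rejected": len(rejected),
        "n_fragments": sum(
            1 for r in accepted if r.verdict == "accept_fragment"
        ),
    }
    logger.info("screen: %d accepted / %d input", len(accepted), len(records))
    return [r.seq_id for r in accepted]


def _report_row(rep, status: str, reason: str) -> dict:
    return {
        "seq_id": rep.seq_id,
        "status": status,
        "reason": reason,
        "verdict": rep.verdict,
        "rossman_found": rep.rossman.found,
        "rossman_position": rep.rossman.position,
        "tyr_position": rep.yk.tyr_position,
        "lys_position": rep.yk.lys_position,
        "cys_position": rep.cys.position,
        "n_truncated": rep.n_truncated,
    }


def _stage_trim(config: PipelineConfig, out: Path, report: dict) -> Alignment:
    try:
        aln = Alignment.from_fasta(config.alignment)
    except (OSError, InputError) as exc:
        raise PipelineError("trim", str(exc)) from exc
    trimmed, kept = trim_core(
        aln, config.trim.max_gap_fraction, config.trim.max_x_fraction
    )
    trimmed.to_fasta(out / "trimmed.fasta")
    report["trim"] = {
        "n_input_columns": aln.ncol,
        "n_kept_columns": len(kept),
        "n_rows": aln.nrow,
    }
    logger.info("trim: kept %d of %d columns", len(kept), aln.ncol)
    return trimmed


def _stage_tree(config: PipelineConfig, out: Path, report: dict):
    meta = {}
    if config.leaf_metadata:
        meta = read_leaf_metadata(config.leaf_metadata)
    if config.stages.tree == "input":
        if not config.tree:
            raise PipelineError("tree", "stages.tree is 'input' but no tree path set")
        try:
            with open(config.tree) as fh:
                tree = parse_newick(fh.read(), meta)
        except (OSError, InputError) as exc:
            raise PipelineError("tree", str(exc)) from exc
    elif config.stages.tree == "nj":
        if not config.alignment:
            raise PipelineError("tree", "stages.tree is 'nj' but no alignment set")
        aln = Alignment.from_fasta(config.alignment)
        labels, dist = pairwise_distance_matrix(aln)
        tree = nj_build(dist, labels)
        tree.meta.update(meta)
    else:
        raise PipelineError("tree", f"unknown tree stage mode {config.stages.tree!r}")

    outgroup = [
        name for name in tree.leaf_names()
        if tree.lineage_of(name) == config.events.outgroup_lineage
    ]
    if outgroup and set(outgroup) != set(tree.leaf_names()):
        try:
            tree = root_on_outgroup(tree, outgroup)
        except InputError as exc:
            raise PipelineError("tree", str(exc)) from exc
    with open(out / "tree.nwk", "w") as fh:
        fh.write(write_newick(tree) + "\n")
    report["tree"] = {
        "n_leaves": len(tree.leaf_names()),
        "rooted": tree.rooted,
        "outgroup_size": len(outgroup),
    }
    return tree


def _stage_events(config: PipelineConfig, tree, out: Path, report: dict) -> None:
    p = config.events
    if not tree.rooted:
        raise PipelineError(
            "events",
            "tree is unrooted and no outgroup leaves were found "
            f"for lineage {p.outgroup_lineage!r}",
        )
    dups = detect_duplications(tree, p.min_shared, p.support_threshold)
    duplication_calls_table(dups).to_csv(
        out / "duplications.tsv", sep="\t", index=False
    )
    origins = assign_origins(
        tree, p.donor_map,
        support_threshold=p.support_threshold,
        purity_threshold=p.purity_threshold,
        min_context=p.min_context,
    )
    origin_calls_table(origins).to_csv(out / "origins.tsv", sep="\t", index=False)
    by_mode: dict[str, int] = {}
    for call in origins:
        by_mode[call.mode] = by_mode.get(call.mode, 0) + 1
    report["events"] = {
        "n_duplications": len(dups),
        "origin_calls": dict(sorted(by_mode.items())),
    }
    logger.info("events: %d duplication call(s), %s origins", len(dups), by_mode)


def _stage_lipor(config: PipelineConfig, out: Path, report: dict) -> None:
    try:
        records = parse_complement_table(config.complement_table)
    except (OSError, InputError) as exc:
        raise PipelineError("lipor", str(exc)) from exc
    if not records:
        raise PipelineError("lipor", "complement table is empty")
    complement_table(records).to_csv(
        out / "complement_classes.tsv", sep="\t", index=False
    )
    summarize_by_group(records).to_csv(
        out / "complement_summary.tsv", sep="\t", index=False
    )
    try:
        assoc = por_lipor_association(records)
        pd.DataFrame(
            assoc.table,
            index=["por>=2", "por<=1"],
            columns=["lipor_reduced", "lipor_complete"],
        ).to_csv(out / "association.tsv", sep="\t")
        report["lipor_association"] = {
            "table": assoc.table.tolist(),
            "p_value": assoc.p_value,
            "n_included": assoc.n_included,
            "n_excluded": assoc.n_excluded,
        }
    except InputError as exc:
        logger.warning("lipor association skipped: %s", exc)
    report["lipor"] = {"n_species": len(records)}


def _stage_primers(config: PipelineConfig, out: Path, report: dict) -> None:
    p = config.primers
    aln = Alignment.from_fasta(config.alignment)
    blocks = find_conserved_blocks(aln, p.window_aa, p.top_k)
    rows = []
    for start, score in blocks:
        for orientation in ("forward", "reverse"):
            try:
                primer = build_primer(
                    aln, start, p.window_aa, orientation, p.tail,
                    p.max_degeneracy,
                )
            except Exception as exc:
                logger.warning(
                    "primer at column %d (%s) rejected: %s",
                    start, orientation, exc,
                )
                continue
            rows.append(
                {
                    "start_column": start,
                    "window_aa": p.window_aa,
                    "conservation": round(score, 4),
                    "orientation": orientation,
                    "sequence": primer.sequence,
                    "degeneracy": primer.degeneracy,
                }
            )
    pd.DataFrame(rows).to_csv(out / "primers.tsv", sep="\t", index=False)
    report["primers"] = {"n_candidates": len(rows)}
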