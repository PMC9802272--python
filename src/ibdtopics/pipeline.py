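"""End-to-end pipeline: ingest -> relevance -> clean -> distress -> topics
-> network -> report, with a run manifest for provenance.

The pipeline config is one YAML file:

.. code-block:: yaml

    input: corpus.jsonl          # or a `synth:` block instead
    output_dir: out/
    seed: 7
    fp_mode: overlap             # overlap | veto | off
    lexicons: lexicons.yaml      # optional; defaults ship with the package

Each stage's output is persisted so partial re-runs are possible; the
manifest records config hashes, seeds, per-stage filter reports, package
version, and paths, and is sufficient to re-run identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import __version__
from .corpus import Corpus, read_corpus, write_corpus
from .filters import (
    FilterReport,
    dedup_same_user,
    distress_filter,
    relevance_filter,
    remove_retweets,
)
from .lexicons import (
    default_distress,
    default_false_positives,
    default_relevance,
    default_topics,
    load_config,
)
from .network import build_network, cooccurrence_matrix, export_sociogram, rank_centrality
from .report import summarize
from .synth import GeneratorConfig, generate
from .topics import classify_corpus, write_assignments

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception | str):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclasses.dataclass
class RunManifest:
    config_hash: str
    seed: int | None
    package_version: str
    started: str
    finished: str = ""
    stages: dict[str, dict] = dataclasses.field(default_factory=dict)
    outputs: dict[str, str] = dataclasses.field(default_factory=dict)

    def record(self, stage: str, report: FilterReport | dict) -> None:
        if stage in self.stages:
            raise PipelineError(stage, "stage recorded twice in manifest")
        self.stages[stage] = (
            report.to_json() if isinstance(report, FilterReport) else report
        )

    def write(self, path: Path) -> Path:
        path.write_text(
            json.dumps(dataclasses.asdict(self), indent=2) + "\n", encoding="utf-8"
        )
        return path


def _load_lexicons(config: dict) -> dict:
    lex: dict = {}
    if config.get("use_default_lexicons", True):
        lex = {
            "relevance": default_relevance(),
            "distress": default_distress(),
            "topics": default_topics(),
            "false_positives": default_false_positives(),
        }
    path = config.get("lexicons")
    if path:
        lex.update(load_config(path))
    required = {"relevance", "distress"} - set(lex)
    if required:
        raise ValueError(f"missing lexicon section(s): {sorted(required)}")
    return lex


def run_pipeline(config: dict | str | Path, output_dir: str | Path | None = None) -> RunManifest:
    """Execute every stage in order and persist all artifacts.

    ``config`` is a YAML path or an equivalent dict.  Raises
    :class:`PipelineError` naming the failing stage on any error.
    """
    if not isinstance(config, dict):
        with open(config, "r", encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    out = Path(output_dir or config.get("output_dir", "pipeline_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = config.get("seed")
    manifest = RunManifest(
        config_hash=hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        seed=seed,
        package_version=__version__,
        started=datetime.now(timezone.utc).isoformat(),
    )

    # -- ingest -------------------------------------------------------------
    try:
        if "synth" in config:
            synth_cfg = dict(config["synth"])
            if seed is not None:
                synth_cfg.setdefault("seed", seed)
            corpus = generate(GeneratorConfig(**synth_cfg))
        elif "input" in config:
            corpus = read_corpus(config["input"], config.get("input_format", "jsonl"))
        else:
            raise ValueError("config needs an 'input' path or a 'synth' block")
        manifest.record("ingest", {"N": corpus.N, "provenance": corpus.provenance})
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("ingest", exc) from exc

    try:
        lex = _load_lexicons(config)
    except Exception as exc:
        raise PipelineError("lexicons", exc) from exc

    def stage(name, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:
            raise PipelineError(name, exc) from exc

    corpus, rep = stage("relevance", relevance_filter, corpus, lex["relevance"])
    manifest.record("relevance", rep)
    corpus, rep = stage("retweets", remove_retweets, corpus)
    manifest.record("retweets", rep)
    corpus, rep = stage("dedup", dedup_same_user, corpus)
    manifest.record("dedup", rep)
    corpus, rep = stage("distress", distress_filter, corpus, lex["distress"])
    manifest.record("distress", rep)
    manifest.outputs["corpus"] = str(
        write_corpus(corpus, out / "filtered_corpus.jsonl")
    )

    # -- topics -------------------------------------------------------------
    try:
        if "topics" not in lex or not lex["topics"].topics:
            raise ValueError("no topic lexicon configured")
        assignments = classify_corpus(
            corpus, lex["topics"], lex.get("false_positives"),
            fp_mode=config.get("fp_mode", "overlap"),
        )
        write_assignments(assignments, out / "assignments.jsonl")
        manifest.outputs["assignments"] = str(out / "assignments.jsonl")
        manifest.record("topics", {
            "n_posts": len(assignments),
            "fp_mode": config.get("fp_mode", "overlap"),
            "n_assigned": sum(1 for a in assignments if a.topics),
        })
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("topics", exc) from exc

    # -- network ------------------------------------------------------------
    try:
        net = build_network(assignments, topics=lex["topics"].topic_names)
        export_sociogram(net, out / "network.graphml", "graphml")
        export_sociogram(net, out / "network_edges.csv", "edgelist_csv")
        export_sociogram(net, out / "network.dot", "dot")
        cooccurrence_matrix(net).to_csv(out / "cooccurrence_matrix.csv")
        manifest.outputs["network"] = str(out / "network.graphml")
        manifest.record("network", {
            "n_multitopic_posts": net.n_multitopic_posts,
            "total_edge_weight": net.total_weight,
            "centrality": rank_centrality(net),
        })
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("network", exc) from exc

    # -- report -------------------------------------------------------------
    try:
        summary = summarize(corpus, assignments, topics=lex["topics"].topic_names)
        summary.write_json(out / "summary.json")
        (out / "summary.txt").write_text(summary.render_text() + "\n", encoding="utf-8")
        manifest.outputs["summary"] = str(out / "summary.json")
        manifest.record("report", {p: s.N for p, s in summary.platforms.items()})
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("report", exc) from exc

    manifest.finished = datetime.now(timezone.utc).isoformat()
    manifest.write(out / "manifest.json")
    return manifest
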