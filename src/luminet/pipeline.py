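"""End-to-end pipeline orchestration with a reproducibility manifest.

``run_pipeline`` chains the discovery stages in order — simulate, scale,
rank, select panel, infer interactions, filter, hub/ego extraction,
export — and/or the cohort-statistics stage, writing every artifact plus a
manifest (package version, seed, parameters, SHA-256 of each artifact) to
a run directory so reruns can be verified bit-for-bit. One global seed
deterministically spawns per-stage seeds, so individual stages can be
rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import luminet
from luminet import io as lio
from luminet._seeds import derive_seed
from luminet.biomarker_ranking import rank_probes, scores_to_frame, select_panel
from luminet.cohort_stats import association_screen, cox_ph, log_rank_test, screen_to_frame
from luminet.exceptions import ConfigError
from luminet.interaction_inference import infer_interactions, pair_table
from luminet.mlp_core import TrainingConfig, scale_to_unit
from luminet.network_model import ego_interactome, export_network, filter_top_edges, find_hubs
from luminet.synthetic_data import CohortConfig, ExpressionConfig, generate_cohort, generate_expression

logger = logging.getLogger("luminet")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    The defaults run a scaled-down demonstration (small matrix, few
    training epochs) that completes in minutes on one CPU; production runs
    raise ``n_iterations``/``n_models``/``max_epochs`` toward the classical
    settings (50 ranking reiterations, 3000-epoch cap, 1000-epoch
    patience).
    """

    out_dir: str = "luminet_run"
    seed: int = 0
    # stage toggles
    run_expression: bool = True
    run_cohort: bool = True
    # optional external inputs (otherwise simulated)
    expression_path: str | None = None
    labels_path: str | None = None
    cohort_path: str | None = None
    # generators
    expression: ExpressionConfig | None = None
    cohort: CohortConfig | None = None
    # training
    n_hidden: int = 2
    learning_rate: float = 0.1
    momentum: float = 0.5
    max_epochs: int = 100
    patience_epochs: int = 50
    # stage parameters
    n_iterations: int = 5
    panel_size: int = 20
    n_models: int = 2
    n_positive: int = 100
    n_negative: int = 100
    hub_min_interactions: int = 6
    ego_k: int = 10
    exposure: str = "exposure"
    markers: tuple[str, ...] = ()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages and write artifacts plus a manifest."""
    for attr in ("expression_path", "labels_path", "cohort_path"):
        p = getattr(config, attr)
        if p is not None and not Path(p).exists():
            raise ConfigError(f"{attr} does not exist: {p}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    train_cfg = TrainingConfig(
        n_hidden=config.n_hidden,
        learning_rate=config.learning_rate,
        momentum=config.momentum,
        max_epochs=config.max_epochs,
        patience_epochs=config.patience_epochs,
        seed=derive_seed(config.seed, "train"),
    )

    if config.run_expression:
        if config.expression_path is not None:
            dataset = lio.read_expression(config.expression_path)
            labels = None
            if config.labels_path is not None:
                labels = (
                    lio.read_labels(config.labels_path)
                    .reindex(dataset.sample_ids)
                    .to_numpy()
                )
            dataset.labels = labels
            dataset.__post_init__()
        else:
            expr_cfg = config.expression or ExpressionConfig(
                seed=derive_seed(config.seed, "expression")
            )
            dataset, truth = generate_expression(expr_cfg)
            (out / "ground_truth_expression.json").write_text(truth.to_json())
            artifacts.append(out / "ground_truth_expression.json")
            artifacts.append(lio.write_expression(dataset, out / "expression.tsv"))
            artifacts.append(
                lio.write_labels(dataset.sample_ids, dataset.labels, out / "labels.tsv")
            )
        logger.info("expression stage: %d probes x %d samples", dataset.n_probes, dataset.n_samples)

        scaled = scale_to_unit(dataset)
        scores = rank_probes(scaled, config=train_cfg, n_iterations=config.n_iterations)
        frame = scores_to_frame(scores)
        frame.to_csv(out / "probe_scores.tsv", sep="\t", index=False)
        artifacts.append(out / "probe_scores.tsv")

        panel = select_panel(scores, k=min(config.panel_size, len(scores)))
        (out / "panel.txt").write_text("\n".join(panel) + "\n")
        artifacts.append(out / "panel.txt")

        matrix = infer_interactions(
            scaled.subset_probes(panel), config=train_cfg, n_models=config.n_models
        )
        pairs = pair_table(matrix)
        pairs.to_csv(out / "interactions.tsv", sep="\t", index=False)
        artifacts.append(out / "interactions.tsv")

        net = filter_top_edges(pairs, config.n_positive, config.n_negative)
        find_hubs(net, config.hub_min_interactions)
        artifacts.append(export_network(net, out / "network.graphml", "graphml"))
        artifacts.append(export_network(net, out / "network.sif", "sif"))
        artifacts.append(export_network(net, out / "network_edges.tsv", "edge-tsv"))
        (out / "hubs.txt").write_text("\n".join(sorted(net.hubs)) + "\n")
        artifacts.append(out / "hubs.txt")

        focal = panel[0]
        ego = ego_interactome(matrix, focal, config.ego_k)
        artifacts.append(
            export_network(ego, out / f"ego_{focal}.tsv", "edge-tsv")
        )
        logger.info(
            "network stage: %d edges, %d hubs, ego around %s",
            len(net.edges), len(net.hubs), focal,
        )

    if config.run_cohort:
        if config.cohort_path is not None:
            cohort = lio.read_cohort(config.cohort_path)
            markers = list(config.markers)
        else:
            cohort_cfg = config.cohort or CohortConfig(
                seed=derive_seed(config.seed, "cohort")
            )
            cohort, ctruth = generate_cohort(cohort_cfg)
            (out / "ground_truth_cohort.json").write_text(ctruth.to_json())
            artifacts.append(out / "ground_truth_cohort.json")
            artifacts.append(lio.write_cohort(cohort, out / "cohort.tsv"))
            markers = list(config.markers) or list(cohort_cfg.marker_list)

        screen = association_screen(cohort, config.exposure, markers)
        screen_to_frame(screen).to_csv(out / "association_screen.tsv", sep="\t", index=False)
        artifacts.append(out / "association_screen.tsv")

        stat, df, p = log_rank_test(cohort, group_col=config.exposure)
        cox = cox_ph(cohort, [config.exposure])
        survival = {
            "log_rank": {"chi_square": stat, "df": df, "p": p},
            "cox": cox.reset_index().to_dict(orient="records"),
        }
        (out / "survival.json").write_text(json.dumps(survival, indent=2))
        artifacts.append(out / "survival.json")
        logger.info("cohort stage: log-rank chi2=%.3f (p=%.3g)", stat, p)

    manifest = {
        "package": "luminet",
        "version": luminet.__version__,
        "seed": config.seed,
        "parameters": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
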