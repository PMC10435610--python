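"""End-to-end orchestration: spectral -> graph -> stats, with a run manifest.

Every intermediate artifact is written to the output directory:

* per subject-timepoint: one PLI matrix and one backbone per band, the
  supra-adjacency matrix (with JSON sidecar), the centrality vector, and
  the subnetwork mean;
* cohort level: paired change tests, covariate screens, and one backward
  regression JSON per executive-functioning test;
* a manifest recording the resolved config, input digests, and per-stage
  record counts.

Reruns with identical inputs and config produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .graph import (
    SubnetworkDefinition,
    build_multiplex,
    multilayer_eigenvector_centrality,
    spanning_backbone,
    subnetwork_mean,
)
from .io import (
    read_node_set,
    read_timeseries,
    write_json,
    write_matrix_tsv,
    write_vector_tsv,
)
from .spectral import TimeSeries, pli_matrix, segment_epochs
from .stats import (
    backward_regression,
    bonferroni_threshold,
    change_scores,
    paired_change_test,
    screen_covariates,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "RunManifest", "analyze_recording", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage and subject/timepoint."""

    def __init__(self, stage: str, ident: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for {ident}: {cause}")
        self.stage = stage
        self.ident = ident
        self.cause = cause


@dataclass
class RunManifest:
    version: str
    config: dict
    input_digests: dict[str, str]
    started: str
    finished: str
    stage_counts: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "tool_version": self.version,
            "config": self.config,
            "input_digests": self.input_digests,
            "started": self.started,
            "finished": self.finished,
            "stage_counts": self.stage_counts,
        }


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def analyze_recording(
    ts: TimeSeries,
    config: PipelineConfig,
    subnet: SubnetworkDefinition,
    out_dir: Path | None = None,
    ident: str = "recording",
):
    """Spectral + graph stages for one recording; returns the subnetwork
    mean centrality and, when ``out_dir`` is set, writes every artifact."""
    t0 = time.perf_counter()
    epochs = segment_epochs(ts, config.epoch_length, config.max_epochs)
    conns = [
        pli_matrix(epochs, band, ts.fs, region_labels=ts.region_labels)
        for band in config.bands
    ]
    layers = [spanning_backbone(c) for c in conns]
    mplex = build_multiplex(layers, config.interlayer_weight)
    ec = multilayer_eigenvector_centrality(mplex, config.aggregation)
    subnet_ec = subnetwork_mean(ec, subnet)
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        for conn, layer in zip(conns, layers):
            write_matrix_tsv(
                out_dir / f"pli_{conn.band.name}.tsv",
                conn.weights, conn.region_labels,
            )
            write_matrix_tsv(
                out_dir / f"backbone_{layer.band}.tsv",
                layer.adjacency, layer.region_labels,
            )
        supra_labels = [
            f"{band}:{lab}"
            for band in mplex.layer_order for lab in mplex.region_labels
        ]
        write_matrix_tsv(out_dir / "supra.tsv", mplex.supra, supra_labels,
                         sig_digits=12)
        write_json(out_dir / "supra.json", {
            "layer_order": mplex.layer_order,
            "N": mplex.n_nodes,
            "L": mplex.n_layers,
            "interlayer_weight": mplex.interlayer_weight,
            "aggregation": ec.aggregation,
            "normalization": config.normalization,
        })
        write_vector_tsv(out_dir / "centrality.tsv", ec.values,
                         ec.region_labels, column="ec")
        write_json(out_dir / "subnet_ec.json", {
            "subnet": subnet.name,
            "n_nodes": len(subnet.node_indices),
            "mean_ec": subnet_ec,
            "eigenvalue": ec.eigenvalue,
        })
    logger.info(
        "analyze_recording ident=%s n_epochs=%d n_bands=%d subnet_ec=%.6f "
        "elapsed=%.2fs",
        ident, len(epochs), len(config.bands), subnet_ec,
        time.perf_counter() - t0,
    )
    return subnet_ec, conns, layers, mplex, ec


def _cohort_stats(
    cohort: pd.DataFrame, config: PipelineConfig, out_dir: Path
) -> dict[str, int]:
    """Paired tests, screening, and backward regressions; one JSON per EF
    test plus a change-test summary."""
    counts: dict[str, int] = {}
    specs = config.covariate_specs()
    records = change_scores(cohort, config.ef_tests)
    counts["change_records"] = len(records)
    threshold = bonferroni_threshold(config.alpha, config.m_tests)

    t1 = cohort[cohort["timepoint"] == "T1"].set_index("subject_id")
    t2 = cohort[cohort["timepoint"] == "T2"].set_index("subject_id")
    both = t1.index.intersection(t2.index)

    paired_payload = {"bonferroni_threshold": round(threshold, 4), "tests": {}}
    for col in ["ec_fpn", *config.ef_tests]:
        try:
            res = paired_change_test(
                t1.loc[both, col].to_numpy(), t2.loc[both, col].to_numpy()
            )
        except ValueError as exc:
            paired_payload["tests"][col] = {"error": str(exc)}
            continue
        paired_payload["tests"][col] = {
            "test_used": res.test_used,
            "statistic": res.statistic,
            "p_value": res.p_value,
            "n_pairs": res.n_pairs,
            "significant_bonferroni": bool(res.p_value < threshold),
        }
    write_json(out_dir / "paired_tests.json", paired_payload)

    n_regressions = 0
    for test in config.ef_tests:
        candidates = [specs[name] for name in config.candidate_covariates
                      if name in specs]
        screens = screen_covariates(t1.reset_index(), test, candidates,
                                    config.alpha) if candidates else []
        selected = [s.name for s in screens if s.selected]
        predictor_names = ["ec_fpn", *config.forced_covariates, *selected]
        predictor_names = list(dict.fromkeys(predictor_names))
        frame = t1.loc[:, [test, *predictor_names]].dropna()
        try:
            reg = backward_regression(
                frame[test], frame[predictor_names], specs,
                config.elimination_threshold,
            )
            payload = reg.to_dict()
        except ValueError as exc:
            payload = {"dependent": test, "error": str(exc)}
        payload["screened"] = [
            {"name": s.name, "test_used": s.test_used, "p_value": s.p_value,
             "selected": s.selected} for s in screens
        ]
        payload["bonferroni_threshold"] = round(threshold, 4)
        write_json(out_dir / f"regression_{test}.json", payload)
        n_regressions += 1
    counts["regressions"] = n_regressions
    return counts


def run_pipeline(
    config: PipelineConfig,
    recordings: list[tuple[str, str, object]],
    cohort_covariates: pd.DataFrame | None,
    out_dir: str | Path,
) -> RunManifest:
    """Run spectral -> graph -> stats over a cohort of recordings.

    Parameters
    ----------
    recordings
        Tuples ``(subject_id, timepoint, source)`` where ``source`` is a
        file path or an in-memory :class:`TimeSeries`.
    cohort_covariates
        Table with ``subject_id``, ``timepoint``, EF Z-score and covariate
        columns; joined with the pipeline-computed ``ec_fpn``. ``None``
        skips the stats stage.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    if config.subnet_file is None:
        raise ValueError("config.subnet_file is required to average "
                         "subnetwork centrality")
    subnet_path = Path(config.subnet_file)
    if not subnet_path.exists():
        raise FileNotFoundError(
            f"subnet file not found: {subnet_path} (checked before any "
            "computation)"
        )
    subnet_labels = read_node_set(subnet_path)

    digests: dict[str, str] = {str(subnet_path): _digest(subnet_path)}
    counts: dict[str, int] = {"recordings": len(recordings)}
    ec_rows: list[dict] = []
    for subject_id, timepoint, source in recordings:
        ident = f"{subject_id}/{timepoint}"
        try:
            if isinstance(source, TimeSeries):
                ts = source
            else:
                ts = read_timeseries(source, fs=config.fs_hz)
                digests[str(source)] = _digest(Path(source))
            subnet = SubnetworkDefinition.from_labels(
                subnet_path.stem, subnet_labels, ts.region_labels
            )
            subnet_ec, *_ = analyze_recording(
                ts, config, subnet,
                out_dir=out_dir / subject_id / timepoint, ident=ident,
            )
        except Exception as exc:
            raise PipelineError("spectral/graph", ident, exc) from exc
        ec_rows.append(
            {"subject_id": subject_id, "timepoint": timepoint,
             "ec_fpn": subnet_ec}
        )
    ec_table = pd.DataFrame(ec_rows)
    ec_table.to_csv(out_dir / "ec_fpn.csv", index=False)
    counts["centrality_values"] = len(ec_table)

    if cohort_covariates is not None:
        cohort = cohort_covariates.drop(
            columns=[c for c in ("ec_fpn",) if c in cohort_covariates.columns]
        ).merge(ec_table, on=["subject_id", "timepoint"], how="inner")
        dropped = len(cohort_covariates) - len(cohort)
        counts["cohort_rows"] = len(cohort)
        counts["cohort_rows_without_recording"] = dropped
        cohort.to_csv(out_dir / "cohort.csv", index=False)
        try:
            counts.update(_cohort_stats(cohort, config, out_dir))
        except Exception as exc:
            raise PipelineError("stats", "cohort", exc) from exc

    manifest = RunManifest(
        version=__version__,
        config=config.to_dict(),
        input_digests=digests,
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
        stage_counts=counts,
    )
    write_json(out_dir / "manifest.json", manifest.to_dict())
    return manifest
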