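"""End-to-end analysis pipeline.

read -> nondetect replacement -> closure -> per-group summaries ->
variation matrix -> permutation covariability report -> divisive + fuzzy
clustering on Aitchison distances -> FC contribution matrix, with every
artifact serialised to an output directory and a manifest recording
parameters, seeds and the input checksum.  A single master seed fans out to
per-stage seeds through stable hashing, so one integer fixes the whole run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import DivisiveClustering, FuzzyClustering, fc_matrix
from .compositional import (
    DEFAULT_K,
    aitchison_distance_matrix,
    closure_matrix,
    replace_below_detection,
    variation_matrix,
)
from .covariability import CovariabilityClassifier
from .io import ConcentrationTable, checksum, read_concentration_table, read_detection_limits
from .summary import summary_table

__all__ = ["RunConfig", "run", "PipelineError"]

log = logging.getLogger("mosscoda")

ARTIFACTS = (
    "summary.csv",
    "variation_matrix.csv",
    "labels.csv",
    "pearson.csv",
    "dendrogram.nwk",
    "memberships.csv",
    "fc_matrix.csv",
    "manifest.json",
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    input: str
    output_dir: str
    detection_limits: str | None = None
    k: float = DEFAULT_K
    n_perm: int = 999
    seed: int = 0
    alpha_low: float = 0.01
    alpha_high: float = 0.99
    p_level: float = 0.02
    n_clusters: int = 2
    membership_exponent: float = 2.0
    nondetect_fraction: float = 0.65
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def validate(self) -> None:
        problems = []
        if not Path(self.input).exists():
            problems.append(f"input file not found: {self.input}")
        if self.detection_limits and not Path(self.detection_limits).exists():
            problems.append(f"detection-limit file not found: {self.detection_limits}")
        if self.k <= 0:
            problems.append("k must be positive")
        if self.n_perm < 99:
            problems.append("n_perm must be at least 99")
        if not 0 < self.alpha_low < self.alpha_high < 1:
            problems.append("need 0 < alpha_low < alpha_high < 1")
        if not 0 < self.p_level < 1:
            problems.append("p_level must lie in (0, 1)")
        if self.n_clusters < 2:
            problems.append("n_clusters must be at least 2")
        if self.membership_exponent <= 1:
            problems.append("membership_exponent must exceed 1")
        if not 0 < self.nondetect_fraction < 1:
            problems.append("nondetect_fraction must lie in (0, 1)")
        if problems:
            raise ValueError("invalid run config: " + "; ".join(problems))


def _stage_seed(master: int, stage: str) -> int:
    digest = hashlib.blake2b(f"{master}|{stage}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") >> 1


def run(config: RunConfig, table: ConcentrationTable | None = None) -> dict:
    """Execute the full pipeline; returns (and writes) the run manifest.

    On stage failure all partial outputs are removed and a
    :class:`PipelineError` tagged with the stage name is raised.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = {
        "package": "mosscoda",
        "version": __version__,
        "parameters": asdict(config),
        "stages": {},
    }
    stage = "read"
    try:
        t0 = time.perf_counter()
        if table is None:
            table = read_concentration_table(config.input)
        manifest["input_checksum"] = checksum(config.input)
        log.info("read %d samples x %d elements", *table.values.shape)

        stage = "zero_handling"
        limits = (
            read_detection_limits(config.detection_limits)
            if config.detection_limits
            else None
        )
        positive, replacements = replace_below_detection(
            table.values, limits, fraction=config.nondetect_fraction,
            nondetect=table.nondetect,
        )
        if len(replacements):
            log.warning("replaced %d nondetect cells", len(replacements))
        manifest["stages"]["zero_handling"] = {"replacements": int(len(replacements))}

        stage = "closure"
        closed = closure_matrix(positive, k=config.k)

        stage = "summary"
        summary = summary_table(positive, table.site_class)
        if table.site_class is None:
            log.info("no site_class metadata: single-group summary, no comparison")
        summary.to_csv(out_dir / "summary.csv", index=False)
        written.append(out_dir / "summary.csv")

        stage = "variation_matrix"
        tmat = variation_matrix(closed)
        tmat.to_csv(out_dir / "variation_matrix.csv")
        written.append(out_dir / "variation_matrix.csv")

        stage = "covariability"
        clf = CovariabilityClassifier(
            n_perm=config.n_perm,
            alpha_low=config.alpha_low,
            alpha_high=config.alpha_high,
            p_level=config.p_level,
            random_state=_stage_seed(config.seed, "covariability"),
        ).fit(positive)
        report = clf.report()
        report.labels.to_csv(out_dir / "labels.csv")
        report.pearson.to_csv(out_dir / "pearson.csv")
        written += [out_dir / "labels.csv", out_dir / "pearson.csv"]
        provenance = {
            "r_critical": report.r_critical,
            "n_samples": report.n_samples,
            "pairs": report.provenance.to_dict(orient="records"),
        }
        (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=1))
        written.append(out_dir / "provenance.json")
        manifest["stages"]["covariability"] = {
            "n_perm": config.n_perm,
            "r_critical": report.r_critical,
        }

        stage = "clustering"
        dist = aitchison_distance_matrix(closed)
        diana = DivisiveClustering(n_clusters=config.n_clusters).fit(dist)
        (out_dir / "dendrogram.nwk").write_text(diana.dendrogram_.to_newick() + "\n")
        written.append(out_dir / "dendrogram.nwk")
        fanny = FuzzyClustering(
            n_clusters=config.n_clusters,
            membership_exponent=config.membership_exponent,
            random_state=_stage_seed(config.seed, "fuzzy"),
        ).fit(dist)
        if not fanny.converged_:
            log.warning("fuzzy clustering did not converge")
        memberships = pd.DataFrame(
            fanny.membership_,
            index=closed.index,
            columns=[f"cluster_{v + 1}" for v in range(config.n_clusters)],
        )
        memberships.to_csv(out_dir / "memberships.csv")
        written.append(out_dir / "memberships.csv")
        fc = fc_matrix(fanny, positive)
        fc_out = fc.fc.T
        fc_out["component_ratio"] = fc.component_ratio
        if fc.cluster_ratio is not None:
            fc_out["cluster_ratio"] = fc.cluster_ratio
        fc_out["dominant_cluster"] = fc.dominant_cluster
        fc_out.index.name = "element"
        fc_out.to_csv(out_dir / "fc_matrix.csv")
        written.append(out_dir / "fc_matrix.csv")
        manifest["stages"]["clustering"] = {
            "fuzzy_converged": bool(fanny.converged_),
            "fuzzy_objective": float(fanny.objective_),
            "n_splits": int(len(diana.heights_)),
        }
        manifest["stages"]["read"] = {
            "n_samples": int(table.values.shape[0]),
            "n_elements": int(table.values.shape[1]),
            "elapsed_s": round(time.perf_counter() - t0, 3),
        }
        manifest["artifacts"] = sorted(p.name for p in written) + ["manifest.json"]
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        log.info("pipeline complete: %d artifacts in %s", len(manifest["artifacts"]), out_dir)
        return manifest
    except Exception as exc:  # clean partial outputs, tag the stage
        for p in written:
            p.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc
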