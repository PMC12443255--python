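"""End-to-end pipeline: simulate -> encode/embed -> balance -> train ->
evaluate -> explain, with file-based stage hand-offs.

Each stage writes its artifacts into the run directory so every step is
independently re-runnable from the CLI; a JSON run log records seeds,
per-stage counts and the ANBS iteration trace. Every random draw derives
from the single master seed via a seed sequence, so a rerun with the same
config is byte-identical in its metric summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .attribution import (
    aggregate_by_residue,
    global_shap_weights,
    shap_res,
    write_attribution_report,
)
from .embeddings import embed_residues, mock_backend, pool_sequence
from .encoders import FeatureMatrix, encode_dataset
from .ensemble_model import EnsembleConfig, save_ensemble, train_ensemble
from .evaluation import cross_validate
from .sampling import AnbsConfig, LabeledMatrix, anbs
from .sequence_io import read_fasta, write_fasta
from .synthetic_data import SequenceSpec, make_sequences

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Declarative pipeline configuration; every value lands in the run log."""

    seed: int = 0
    # simulate
    n_pos: int = 200
    n_neg: int = 600
    enrichment_factor: float = 3.0
    # features: "aac" | "dc" | "paac" | "ctd" | "embed"
    encoder: str = "aac"
    embed_dim: int = 64
    # balance
    sampler: Optional[str] = "anbs"  # "anbs" | "adasyn" | None
    max_ratio: float = 1.0
    max_iter: int = 100
    k: int = 5
    # train / evaluate
    members: tuple[str, ...] = ("random_forest", "gradient_boosting", "hist_gradient_boosting")
    member_params: dict = field(default_factory=dict)
    folds: int = 10
    resample_mode: str = "safe"
    # explain
    explain: bool = True
    shap_samples: int = 10
    shap_background: int = 60

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.members, list):
            cfg.members = tuple(cfg.members)
        return cfg


def _stage_seeds(master: int, n: int = 8) -> list[int]:
    return [int(s % (2**31)) for s in np.random.SeedSequence(master).generate_state(n)]


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the configured stages in order, writing all artifacts.

    Returns the run log (also written to ``run_log.json``). Any stage
    failure propagates with the stage name; partial outputs remain on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    log: dict = {"version": __version__, "config": asdict(config), "stages": {}}

    def _fail(stage: str, exc: Exception):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # --- simulate -----------------------------------------------------
    try:
        records = make_sequences(
            SequenceSpec(
                n_pos=config.n_pos,
                n_neg=config.n_neg,
                enrichment_factor=config.enrichment_factor,
                seed=seeds[0],
            )
        )
        write_fasta(records, outdir / "sequences.fasta")
        log["stages"]["simulate"] = {"n_pos": config.n_pos, "n_neg": config.n_neg,
                                     "seed": seeds[0]}
    except Exception as exc:  # noqa: BLE001
        _fail("simulate", exc)

    # --- encode / embed ----------------------------------------------
    try:
        labels = np.array([r.label for r in records])
        embeddings = None
        if config.encoder == "embed":
            backend = mock_backend(dim=config.embed_dim, seed=seeds[1])
            embeddings = [embed_residues(backend, r.sequence) for r in records]
            fm = FeatureMatrix(
                values=np.vstack([pool_sequence(e) for e in embeddings]),
                feature_names=[f"emb_{i}" for i in range(config.embed_dim)],
                row_ids=[r.id for r in records],
                provenance=backend.name,
            )
        else:
            fm = encode_dataset(records, encoder=config.encoder)
        fm.write_csv(outdir / "features.csv")
        log["stages"]["features"] = {"encoder": config.encoder, "dim": fm.values.shape[1]}
    except Exception as exc:  # noqa: BLE001
        _fail("features", exc)

    data = LabeledMatrix(fm.values, labels)

    # --- balance ------------------------------------------------------
    try:
        pre_counts = data.class_counts()
        anbs_trace = None
        if config.sampler == "anbs":
            result = anbs(
                data,
                AnbsConfig(
                    max_ratio=config.max_ratio,
                    max_iter=config.max_iter,
                    k=config.k,
                    seed=seeds[2],
                ),
            )
            balanced = result.data
            anbs_trace = result.iterations
        elif config.sampler == "adasyn":
            from .sampling import adasyn

            balanced = adasyn(data, k=config.k, seed=seeds[2])
        elif config.sampler is None:
            balanced = data
        else:
            raise ValueError(f"unknown sampler {config.sampler!r}")
        post_counts = balanced.class_counts()
        _write_balanced(balanced, fm, outdir / "balanced.csv")
        log["stages"]["balance"] = {
            "sampler": config.sampler,
            "pre_counts": {str(k): v for k, v in pre_counts.items()},
            "post_counts": {str(k): v for k, v in post_counts.items()},
            "anbs_trace": anbs_trace,
            "seed": seeds[2],
        }
    except Exception as exc:  # noqa: BLE001
        _fail("balance", exc)

    # --- train --------------------------------------------------------
    try:
        ens_config = EnsembleConfig(
            members=config.members, seed=seeds[3], member_params=config.member_params
        )
        model = train_ensemble(balanced, ens_config)
        save_ensemble(model, outdir / "model.joblib")
        log["stages"]["train"] = {"members": list(config.members), "seed": seeds[3]}
    except Exception as exc:  # noqa: BLE001
        _fail("train", exc)

    # --- evaluate -----------------------------------------------------
    try:
        cv = cross_validate(
            data,
            config=ens_config,
            folds=config.folds,
            resample_mode=config.resample_mode,
            anbs_config=AnbsConfig(
                max_ratio=config.max_ratio, max_iter=config.max_iter,
                k=config.k, seed=seeds[4],
            ),
            seed=seeds[4],
        )
        cv.write_csv(outdir / "metrics.csv")
        log["stages"]["evaluate"] = {
            "folds": config.folds,
            "mode": config.resample_mode,
            "mean": {k: float(v) for k, v in cv.mean.items()},
            "seed": seeds[4],
        }
    except Exception as exc:  # noqa: BLE001
        _fail("evaluate", exc)

    # --- explain ------------------------------------------------------
    if config.explain and config.encoder == "embed":
        try:
            rng = np.random.default_rng(seeds[5])
            n = data.X.shape[0]
            bg_idx = rng.choice(n, size=min(config.shap_background, n), replace=False)
            expl_idx = rng.choice(n, size=min(config.shap_background, n), replace=False)
            weights = global_shap_weights(
                model,
                background=data.X[bg_idx],
                X_explain=data.X[expl_idx],
                n_samples=config.shap_samples,
                seed=seeds[5],
            )
            results = [shap_res(e, weights) for e in embeddings]
            write_attribution_report(
                outdir / "attribution.tsv", [r.id for r in records], results
            )
            table = aggregate_by_residue(results)
            table.to_csv(outdir / "letter_importance.csv", index=False)
            log["stages"]["explain"] = {
                "top_letters": table["letter"].head(4).tolist(),
                "seed": seeds[5],
            }
        except Exception as exc:  # noqa: BLE001
            _fail("explain", exc)

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return log


def _write_balanced(balanced: LabeledMatrix, fm: FeatureMatrix, path: Path) -> None:
    """Balanced matrix with a provenance column (original / synthetic)."""
    import pandas as pd

    prov = (
        balanced.provenance
        if balanced.provenance is not None
        else np.full(balanced.y.shape[0], "original", dtype=object)
    )
    df = pd.DataFrame(balanced.X, columns=fm.feature_names)
    df.insert(0, "label", balanced.y)
    df.insert(1, "provenance", prov)
    df.to_csv(path, index=False)
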