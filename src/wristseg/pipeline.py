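"""Orchestration: configuration, the end-to-end segmenter, the
threshold-ratio sweep, and the held-out phantom benchmark.

A single top-level seed deterministically derives independent named
substreams for every randomized stage (phantom cohort, swarm, fold
assignment), so a run is reproducible from its config snapshot alone
while stages remain independently reseedable.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics
from .edges import CannyParams, canny_detect, compute_gradient, gaussian_smooth, nonmax_suppress
from .features import FEATURE_NAMES, classify_edges, extract_edge_features, label_edge_pixels
from .phantom import Phantom, PhantomSpec, default_wrist_spec, generate_phantom, noiseless_spec
from .svm import KernelSVC
from .tuning import pso_svm_tune
from .swarm import SwarmConfig

logger = logging.getLogger("wristseg")

__all__ = [
    "PipelineConfig",
    "RunRecord",
    "stage_seed",
    "segment_image",
    "run_segmentation",
    "sweep_ratio",
    "train_on_phantoms",
    "evaluate_phantom",
    "run_benchmark",
    "EdgeLesionSegmenter",
]

PAPER_RATIO_GRID = (0.3, 0.6, 0.9, 1.2, 1.5, 1.8)


def stage_seed(master: int, name: str) -> int:
    """Deterministic per-stage substream seed (< 2**31) from a master seed."""
    tag = int.from_bytes(name.encode()[:4].ljust(4, b"\0"), "big")
    ss = np.random.SeedSequence((int(master), tag))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end pipeline, YAML round-trippable."""

    seed: int = 0
    # Canny
    sigma: float = 1.4
    low: float = 0.12
    ratio: float = 1.8
    relative_thresholds: bool = True
    # phantom cohort
    size: int = 128
    noise_sigma: float = 0.03
    bias_amplitude: float = 0.08
    lesion_contrast: float = 0.28
    # features / mask reconstruction
    window: int = 5
    close_size: int = 3
    # tuning
    folds: int = 3
    n_particles: int = 8
    swarm_iters: int = 10
    cognitive: float = 1.5
    social: float = 1.5
    inertia: float = 0.9
    inertia_final: float | None = 0.4
    max_train_samples: int = 600
    n_train_phantoms: int = 3

    def canny_params(self) -> CannyParams:
        return CannyParams(
            sigma=self.sigma,
            low=self.low,
            ratio=self.ratio,
            relative=self.relative_thresholds,
        )

    def swarm_config(self) -> SwarmConfig:
        return SwarmConfig(
            n_particles=self.n_particles,
            bounds=((-2.0, 4.0), (-4.0, 2.0)),
            cognitive=self.cognitive,
            social=self.social,
            inertia=self.inertia,
            inertia_final=self.inertia_final,
            max_iters=self.swarm_iters,
            seed=stage_seed(self.seed, "swarm"),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class RunRecord:
    """Reproducibility record of one pipeline run."""

    config: dict
    timings: dict = field(default_factory=dict)
    report: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "RunRecord":
        return cls(**json.loads(Path(path).read_text()))


class _Timer:
    def __init__(self, record: RunRecord, stage: str):
        self.record = record
        self.stage = stage

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        dt = time.perf_counter() - self.t0
        self.record.timings[self.stage] = dt
        logger.info("stage %-12s %.3f s", self.stage, dt)


def segment_image(
    img: np.ndarray, model: KernelSVC, config: PipelineConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canny -> features -> classify -> lesion mask.

    Returns ``(edges, lesion_edges, lesion_mask)``.
    """
    params = config.canny_params()
    smoothed = gaussian_smooth(img, params.sigma)
    field_ = compute_gradient(smoothed)
    edges = canny_detect(img, params)
    lesion_edges, lesion_mask = classify_edges(
        img, edges, field_, model, window=config.window, close_size=config.close_size
    )
    return edges, lesion_edges, lesion_mask


def run_segmentation(
    image_path, model_path, config: PipelineConfig, out_dir=None
) -> tuple[np.ndarray, RunRecord]:
    """File-level entry point: read image + model, segment, write mask."""
    from .io import load_model, read_image, write_mask

    record = RunRecord(config=asdict(config))
    with _Timer(record, "load"):
        img = read_image(image_path)
        model, _meta = load_model(model_path)
    with _Timer(record, "segment"):
        edges, lesion_edges, lesion_mask = segment_image(img, model, config)
    record.report = {
        "n_edge_pixels": int(edges.sum()),
        "n_lesion_edge_pixels": int(lesion_edges.sum()),
        "lesion_area": int(lesion_mask.sum()),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        write_mask(out_dir / "lesion_mask.png", lesion_mask)
        write_mask(out_dir / "edges.png", edges)
        record.artifacts = {
            "lesion_mask": str(out_dir / "lesion_mask.png"),
            "edges": str(out_dir / "edges.png"),
        }
        record.to_json(out_dir / "run_record.json")
    return lesion_mask, record


def sweep_ratio(
    img: np.ndarray,
    truth_edges: np.ndarray | None,
    config: PipelineConfig,
    ratios=PAPER_RATIO_GRID,
) -> pd.DataFrame:
    """Edge maps across the high/low threshold ratio grid.

    The low threshold is resolved once on the image's NMS magnitude and
    held fixed across ratios, so only the high threshold moves.  Each
    ratio's edge map is scored with the edge continuity index and, when
    ground truth is supplied, the edge credibility index.
    """
    params = config.canny_params()
    smoothed = gaussian_smooth(img, params.sigma)
    field_ = compute_gradient(smoothed)
    nms = nonmax_suppress(field_)
    t_l = params.low * nms.max() if params.relative else params.low
    rows = []
    for ratio in ratios:
        if ratio <= 0:
            raise ValueError("ratios must be > 0")
        edge_map = canny_detect(
            img,
            CannyParams(sigma=params.sigma, low=t_l, ratio=ratio, relative=False),
        )
        row = {
            "ratio": ratio,
            "n_edge_pixels": int(edge_map.sum()),
            "ci": metrics.edge_continuity(edge_map),
        }
        if truth_edges is not None:
            row["bi"] = metrics.edge_credibility(edge_map, truth_edges)
        rows.append(row)
    return pd.DataFrame(rows)


def _phantom_cohort(config: PipelineConfig, n: int, noiseless: bool = False):
    base = stage_seed(config.seed, "phantom")
    specs = [
        default_wrist_spec(
            seed=base + i,
            size=config.size,
            noise_sigma=config.noise_sigma,
            bias_amplitude=config.bias_amplitude,
            lesion_contrast=config.lesion_contrast,
        )
        for i in range(n)
    ]
    if noiseless:
        specs = [noiseless_spec(s) for s in specs]
    return [generate_phantom(s) for s in specs]


def train_on_phantoms(
    phantoms: list[Phantom], config: PipelineConfig
) -> tuple[KernelSVC, dict]:
    """Detect edges on training phantoms, label them from ground truth,
    subsample, PSO-tune (C, gamma), and fit the final classifier."""
    params = config.canny_params()
    feats = []
    labels = []
    for ph in phantoms:
        smoothed = gaussian_smooth(ph.image, params.sigma)
        field_ = compute_gradient(smoothed)
        edges = canny_detect(ph.image, params)
        f = extract_edge_features(ph.image, edges, field_, window=config.window)
        if len(f) == 0:
            continue
        feats.append(f[list(FEATURE_NAMES)].to_numpy())
        labels.append(label_edge_pixels(f, ph.lesion_mask))
    X = np.vstack(feats)
    y = np.concatenate(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training phantoms produced a single-class edge set")

    rng = np.random.default_rng(stage_seed(config.seed, "subsample"))
    X, y = _stratified_subsample(X, y, config.max_train_samples, rng)

    c_star, gamma_star, cv_acc = pso_svm_tune(
        X,
        y,
        folds=config.folds,
        swarm=config.swarm_config(),
        seed=stage_seed(config.seed, "folds"),
    )
    model = KernelSVC(C=c_star, kernel="rbf", gamma=gamma_star).fit(X, y)
    info = {
        "C": c_star,
        "gamma": gamma_star,
        "cv_accuracy": cv_acc,
        "n_train": int(len(y)),
        "n_positive": int(np.sum(y == 1)),
    }
    logger.info("tuned SVM: %s", info)
    return model, info


def _stratified_subsample(X, y, n_max, rng):
    """Cap the training set size, keeping at least a third positives when
    the positive class is rare."""
    if len(y) <= n_max:
        return X, y
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == -1)
    n_pos = min(len(pos), max(n_max // 3, n_max - len(neg)))
    n_neg = n_max - n_pos
    if n_neg > len(neg):
        n_neg = len(neg)
        n_pos = min(len(pos), n_max - n_neg)
    keep = np.concatenate(
        [
            rng.choice(pos, size=n_pos, replace=False),
            rng.choice(neg, size=n_neg, replace=False),
        ]
    )
    keep.sort()
    return X[keep], y[keep]


def evaluate_phantom(
    ph: Phantom, model: KernelSVC, config: PipelineConfig
) -> metrics.QualityReport:
    """Segment one phantom and score it against its ground truth.

    Fidelity metrics compare the noiseless phantom image with the
    pipeline's smoothed (denoised) image; FOM/CI/BI score the detected
    edge map against the true region boundaries; the diagnostic scores
    compare the reconstructed lesion mask with the true lesion mask
    per-pixel.
    """
    params = config.canny_params()
    denoised = gaussian_smooth(ph.image, params.sigma)
    edges, lesion_edges, lesion_mask = segment_image(ph.image, model, config)
    counts = metrics.confusion(lesion_mask, ph.lesion_mask)
    acc, sen, spe, dsc = metrics.diagnostic_scores(counts)
    return metrics.QualityReport(
        psnr=metrics.psnr(ph.noiseless, denoised),
        mse=metrics.mse(ph.noiseless, denoised),
        fom=metrics.fom(edges, ph.truth_edges),
        ssim=metrics.ssim(ph.noiseless, denoised),
        ci=metrics.edge_continuity(edges),
        bi=metrics.edge_credibility(edges, ph.truth_edges),
        acc=acc,
        sen=sen,
        spe=spe,
        dsc=dsc,
    )


def run_benchmark(
    n: int, config: PipelineConfig, noiseless: bool = False, out_dir=None
) -> dict:
    """Held-out phantom benchmark.

    Generates ``n`` seeded phantoms, trains (with PSO tuning) on the
    first ``config.n_train_phantoms`` and evaluates on the rest,
    reporting mean and SD of every metric plus the tuned
    hyperparameters.  Deterministic for a fixed config.
    """
    if n < 2:
        raise ValueError("benchmark needs n >= 2 phantoms")
    n_train = min(config.n_train_phantoms, n - 1)
    phantoms = _phantom_cohort(config, n, noiseless=noiseless)
    record = RunRecord(config=asdict(config))
    with _Timer(record, "train"):
        model, info = train_on_phantoms(phantoms[:n_train], config)
    reports = []
    with _Timer(record, "evaluate"):
        for ph in phantoms[n_train:]:
            reports.append(evaluate_phantom(ph, model, config))
    table = pd.DataFrame([vars(r) for r in reports])
    finite = table.replace([np.inf, -np.inf], np.nan)
    aggregate = {
        "n_phantoms": n,
        "n_train": n_train,
        "n_test": n - n_train,
        "tuning": info,
        "mean": finite.mean().to_dict(),
        "sd": finite.std(ddof=1).to_dict(),
    }
    record.report = aggregate
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "per_phantom.csv", index=False)
        record.to_json(out_dir / "benchmark.json")
    return aggregate


class EdgeLesionSegmenter:
    """End-to-end estimator: fit on phantoms (or any images with truth
    lesion masks), predict lesion masks for new images.

    Thin object wrapper over :func:`train_on_phantoms` /
    :func:`segment_image` so the whole pipeline composes like an
    sklearn estimator.
    """

    def __init__(self, config: PipelineConfig | None = None):
        self.config = config or PipelineConfig()

    def get_params(self, deep: bool = True) -> dict:
        return {"config": self.config}

    def set_params(self, **params) -> "EdgeLesionSegmenter":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, phantoms: list[Phantom], y=None) -> "EdgeLesionSegmenter":
        self.model_, self.tuning_info_ = train_on_phantoms(phantoms, self.config)
        return self

    def predict(self, img: np.ndarray) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("segmenter is not fitted")
        _, _, mask = segment_image(img, self.model_, self.config)
        return mask
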