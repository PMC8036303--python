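"""Synthetic data with the statistical structure the method assumes.

Every generator here is a pure function of its seed and configuration:
labeled bags of simplex descriptors drawn from class-specific SSD mixtures
(the stand-in for image datasets), seeded texture images that exercise the
feature-extraction path end to end, and a `recovery_experiment` harness that
reruns the parameter-recovery, component-selection and kernel-ordering
studies and reports pass/fail records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .em import fit_em
from .mml import select_k, message_length
from .pipeline import cross_validate
from .ssd import FeatureBag, SSDMixture, SSDParams, mixture_sample, ssd_sample

__all__ = [
    "GroundTruth",
    "default_two_class_ground_truth",
    "well_separated_three_component",
    "recovery_target_component",
    "sample_mixture_bags",
    "make_texture_images",
    "write_texture_pngs",
    "recovery_experiment",
    "DEFAULT_EXPERIMENT_CONFIG",
]


@dataclass(frozen=True)
class GroundTruth:
    """Class-conditional SSD mixtures plus sampling sizes and the master seed."""

    class_models: dict[str, SSDMixture]
    n_images: int = 20
    vectors_per_image: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        dims = {m.dim for m in self.class_models.values()}
        if len(dims) != 1:
            raise ValueError("all class models must share D")
        if self.n_images < 1 or self.vectors_per_image < 1:
            raise ValueError("n_images and vectors_per_image must be >= 1")


def default_two_class_ground_truth(
    n_images: int = 20, vectors_per_image: int = 50, seed: int = 0
) -> GroundTruth:
    """The default two-class condition: D = 3, separable but overlapping.

    Class A: two components with shapes (8,2,2) and (2,8,2), uniform
    location, b = 1.2.  Class B: shapes (2,2,8) and (4,4,4), location
    (0.2, 0.3, 0.5), b = 0.8.  Equal mixing weights throughout.
    """
    uni = np.ones(3) / 3
    a = SSDMixture(
        [0.5, 0.5],
        (SSDParams([8, 2, 2], uni, 1.2), SSDParams([2, 8, 2], uni, 1.2)),
    )
    b = SSDMixture(
        [0.5, 0.5],
        (
            SSDParams([2, 2, 8], [0.2, 0.3, 0.5], 0.8),
            SSDParams([4, 4, 4], [0.2, 0.3, 0.5], 0.8),
        ),
    )
    return GroundTruth(
        {"classA": a, "classB": b}, n_images=n_images,
        vectors_per_image=vectors_per_image, seed=seed,
    )


def well_separated_three_component(dim: int = 3) -> SSDMixture:
    """A well-separated K=3 mixture used by the component-selection study."""
    comps = []
    for k in range(3):
        alpha = np.full(dim, 3.0)
        alpha[k % dim] = 15.0
        comps.append(SSDParams(alpha, np.ones(dim) / dim, 1.0))
    return SSDMixture(np.ones(3) / 3, tuple(comps))


def recovery_target_component() -> SSDParams:
    """The single-component ground truth of the parameter-recovery study."""
    return SSDParams([5.0, 2.0, 3.0], [0.3, 0.3, 0.4], 1.5)


def sample_mixture_bags(gt: GroundTruth) -> tuple[list[FeatureBag], dict[str, str]]:
    """Draw the labeled bags: per image, ancestral sampling from its class mixture.

    Per-image seeds are spawned deterministically from the master seed, so
    the output is a pure function of ``gt``.
    """
    classes = sorted(gt.class_models)
    children = np.random.SeedSequence(gt.seed).spawn(len(classes) * gt.n_images)
    bags, labels = [], {}
    pos = 0
    for cls in classes:
        model = gt.class_models[cls]
        for i in range(gt.n_images):
            vecs = mixture_sample(
                model, gt.vectors_per_image, np.random.default_rng(children[pos])
            )
            image_id = f"{cls}_{i:03d}"
            bags.append(FeatureBag(image_id, vecs))
            labels[image_id] = cls
            pos += 1
    return bags, labels


def make_texture_images(
    n_per_class: int = 10, size: int = 64, seed: int = 0,
) -> tuple[dict[str, np.ndarray], dict[str, str]]:
    """Seeded grayscale textures: smooth low-frequency vs high-frequency speckle."""
    if size < 4:
        raise ValueError("size must be at least 4")
    children = np.random.SeedSequence(seed).spawn(2 * n_per_class)
    images, labels = {}, {}
    pos = 0
    for cls, sigma in (("smooth", 4.0), ("speckle", 0.0)):
        for i in range(n_per_class):
            rng = np.random.default_rng(children[pos])
            field_ = rng.standard_normal((size, size))
            if sigma > 0:
                field_ = gaussian_filter(field_, sigma)
            lo, hi = field_.min(), field_.max()
            img = np.round((field_ - lo) / (hi - lo) * 255).astype(np.uint8)
            image_id = f"{cls}_{i:03d}"
            images[image_id] = img
            labels[image_id] = cls
            pos += 1
    return images, labels


def write_texture_pngs(images: dict[str, np.ndarray], outdir: str | Path) -> list[Path]:
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for image_id, img in images.items():
        p = outdir / f"{image_id}.png"
        iio.imwrite(p, img)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# experiment harness
# ---------------------------------------------------------------------------

DEFAULT_EXPERIMENT_CONFIG: dict = {
    "seed": 0,
    "recovery": {
        "n": 5000,
        "alpha_rel_tol": 0.10,
        "b_rel_tol": 0.10,
        "beta_abs_tol": 0.05,
    },
    "selection": {
        "n": 1000,
        "replicates": 20,
        "k_range": [1, 2, 3, 4, 5],
        "min_rate": 0.8,
        "penalty_replicates": 10,
        "penalty_k_range": [1, 2, 3],
    },
    "ordering": {
        "replicates": 5,
        "n_images": 20,
        "vectors_per_image": 50,
        "folds": 10,
        "n_samples": 2000,
        "min_wins": 4,
        "min_skk_acc": 90.0,
    },
}


def _merge(base: dict, override: dict | None) -> dict:
    out = {k: (v.copy() if isinstance(v, dict) else v) for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def run_parameter_recovery(seed_seq: np.random.SeedSequence, cfg: dict) -> dict:
    """Fit K=1 to data from the known single component; check the errors."""
    true = recovery_target_component()
    data = ssd_sample(true, cfg["n"], np.random.default_rng(seed_seq))
    fit = fit_em(data, 1, seed=0, tol=1e-8, m_step_maxiter=300)
    c = fit.model.components[0]
    alpha_rel = float(np.max(np.abs(c.alpha / true.alpha - 1.0)))
    b_rel = float(abs(c.b / true.b - 1.0))
    beta_abs = float(np.max(np.abs(c.beta - true.beta)))
    monotone = bool(np.all(np.diff(fit.loglik_trace) >= -1e-8))
    passed = (
        alpha_rel <= cfg["alpha_rel_tol"]
        and b_rel <= cfg["b_rel_tol"]
        and beta_abs <= cfg["beta_abs_tol"]
        and monotone
    )
    return {
        "name": "parameter_recovery",
        "passed": bool(passed),
        "alpha_rel_err": alpha_rel,
        "b_rel_err": b_rel,
        "beta_abs_err": beta_abs,
        "loglik_monotone": monotone,
        "n": cfg["n"],
    }


def run_k_selection(seed_seq: np.random.SeedSequence, cfg: dict) -> dict:
    """Replicated MML selection on K=3 data plus the over-K penalty check."""
    gen = well_separated_three_component()
    n_rep = cfg["replicates"]
    children = seed_seq.spawn(n_rep + cfg["penalty_replicates"])
    hits = 0
    for r in range(n_rep):
        rng = np.random.default_rng(children[r])
        data = mixture_sample(gen, cfg["n"], rng)
        rep = select_k(data, cfg["k_range"], seed=int(children[r].generate_state(1)[0] % 2**31))
        hits += rep.best_k == 3
    rate = hits / n_rep

    single = recovery_target_component()
    increasing = 0
    n_pen = cfg["penalty_replicates"]
    for r in range(n_pen):
        rng = np.random.default_rng(children[n_rep + r])
        data = ssd_sample(single, cfg["n"], rng)
        mls = []
        for k in cfg["penalty_k_range"]:
            fit = fit_em(data, k, seed=0)
            mls.append(message_length(fit.model, data))
        increasing += bool(np.all(np.diff(mls) > 0))
    pen_rate = increasing / n_pen
    passed = rate >= cfg["min_rate"] and pen_rate >= cfg["min_rate"]
    return {
        "name": "k_selection",
        "passed": bool(passed),
        "true_k_rate": rate,
        "penalty_increasing_rate": pen_rate,
        "replicates": n_rep,
    }


def run_ordering(seed_seq: np.random.SeedSequence, cfg: dict) -> dict:
    """SSD-mixture SKK kernel vs the Gaussian-mixture kernel baseline."""
    children = seed_seq.spawn(cfg["replicates"])
    ssd_accs, gmm_accs, wins = [], [], 0
    for r in range(cfg["replicates"]):
        rep_seed = int(children[r].generate_state(1)[0] % 2**31)
        gt = default_two_class_ground_truth(
            n_images=cfg["n_images"], vectors_per_image=cfg["vectors_per_image"],
            seed=rep_seed,
        )
        bags, labels = sample_mixture_bags(gt)
        common = dict(
            kernel_type="skk", folds=cfg["folds"], seed=rep_seed,
            n_samples=cfg["n_samples"],
        )
        ssd_rep = cross_validate(bags, labels, model_family="ssd", **common)
        gmm_rep = cross_validate(bags, labels, model_family="gaussian", **common)
        ssd_accs.append(ssd_rep.acc)
        gmm_accs.append(gmm_rep.acc)
        wins += ssd_rep.acc >= gmm_rep.acc
    mean_ssd = float(np.mean(ssd_accs))
    passed = wins >= cfg["min_wins"] and mean_ssd >= cfg["min_skk_acc"]
    return {
        "name": "kernel_ordering",
        "passed": bool(passed),
        "ssd_skk_acc": ssd_accs,
        "gaussian_skk_acc": gmm_accs,
        "mean_ssd_skk_acc": mean_ssd,
        "mean_gaussian_skk_acc": float(np.mean(gmm_accs)),
        "wins": int(wins),
        "replicates": cfg["replicates"],
    }


def recovery_experiment(config: dict | None = None) -> dict:
    """Run the recovery, selection and ordering studies; one record each."""
    cfg = _merge(DEFAULT_EXPERIMENT_CONFIG, config)
    root = np.random.SeedSequence(cfg["seed"])
    s_rec, s_sel, s_ord = root.spawn(3)
    records = [
        run_parameter_recovery(s_rec, cfg["recovery"]),
        run_k_selection(s_sel, cfg["selection"]),
        run_ordering(s_ord, cfg["ordering"]),
    ]
    return {
        "seed": cfg["seed"],
        "all_passed": bool(all(r["passed"] for r in records)),
        "records": records,
    }
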