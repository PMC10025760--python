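"""Synthetic cohorts and toy geometries for exercising the audit pipeline.

Two families of inputs are produced here:

* Two-dimensional *scenario toys* that realize the three canonical task
  inter-relationships used throughout the package — (A) tasks separable on
  disjoint coordinates, (B) tasks sharing both coordinates with orthogonal
  decision boundaries, (C) tasks with highly correlated labels along a shared
  dominant boundary direction.

* Full synthetic *cohorts*: tabular latent features (optionally rendered to
  small grayscale images) with 14 binary disease labels, of which two focal
  labels (``no_finding`` and ``condition_x``) are mutually exclusive, plus
  group / sex / age attributes.  The default configuration mirrors the
  statistical structure of a large public chest X-ray population: three
  unbalanced groups (majority ~78%), a minority group that is on average
  younger, group-dependent sex ratios, and group-dependent prevalence of the
  two focal labels.

The ``encoding`` switch controls how the group attribute enters the latent
features: ``none`` omits it entirely (scenario A analog), ``orthogonal``
places it on directions orthogonal to the disease direction (scenario B
analog), and ``entangled`` correlates it with the disease direction
(scenario C analog).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FOCAL_LABELS",
    "GROUPS",
    "ScenarioToy",
    "CohortConfig",
    "Cohort",
    "composition_shift_config",
    "make_scenario_toy",
    "make_cohort",
    "render_images",
    "summarize_population",
    "save_cohort",
    "load_cohort",
]

FOCAL_LABELS = ("no_finding", "condition_x")
GROUPS = ("g0", "g1", "g2")
SEXES = ("female", "male")
SPLITS = ("train", "val", "test")

# unit vectors at 120 degrees: 2-D simplex embedding of the three groups
_GROUP_SIMPLEX = np.array(
    [[1.0, 0.0], [-0.5, np.sqrt(3) / 2], [-0.5, -np.sqrt(3) / 2]]
)

_U = np.array([1.0, 1.0]) / np.sqrt(2)
_V = np.array([1.0, -1.0]) / np.sqrt(2)


@dataclass
class ScenarioToy:
    """2-D toy with a binary color task and a binary shape task."""

    x: np.ndarray               # (n, 2) coordinates
    color_label: np.ndarray     # (n,) in {0, 1}
    shape_label: np.ndarray     # (n,) in {0, 1}
    scenario: str               # 'A', 'B' or 'C'
    seed: int

    @property
    def n(self) -> int:
        return len(self.color_label)


def make_scenario_toy(
    scenario: str,
    n_per_class: int,
    noise_sd: float = 0.1,
    seed: int = 0,
    *,
    flip_prob: float = 0.02,
    c_offset: float = 0.2,
) -> ScenarioToy:
    """Generate ``4 * n_per_class`` points realizing one task geometry.

    Scenario A: color depends on x1 only (clusters at x1 = +-1), shape on x2
    only.  Scenario B: color boundary normal to u=(1,1)/sqrt(2), shape
    boundary normal to v=(1,-1)/sqrt(2); both tasks need both coordinates and
    the two optimal linear boundaries are orthogonal.  Scenario C: labels are
    highly correlated (flip probability ``flip_prob``); the dominant boundary
    direction u is shared, with a small orthogonal offset ``c_offset`` keeping
    both labels exactly separable at zero noise.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    scenario = str(scenario).upper()
    if scenario not in {"A", "B", "C"}:
        raise ValueError(f"unknown scenario {scenario!r}; expected 'A', 'B' or 'C'")
    rng = np.random.default_rng(seed)
    n = 4 * n_per_class
    combos = np.repeat(np.arange(4), n_per_class)
    color = (combos // 2).astype(int)
    shape = (combos % 2).astype(int)
    c = 2.0 * color - 1.0
    s = 2.0 * shape - 1.0
    if scenario == "A":
        centers = np.column_stack([c, s])
    elif scenario == "B":
        centers = c[:, None] * _U + s[:, None] * _V
    else:  # C: correlated labels, shared dominant direction
        latent = rng.integers(0, 2, size=n)
        color = latent.copy()
        flips = rng.random(n) < flip_prob
        shape = np.where(flips, 1 - latent, latent)
        c = 2.0 * color - 1.0
        s = 2.0 * shape - 1.0
        centers = c[:, None] * _U + c_offset * s[:, None] * _V
    x = centers + noise_sd * rng.standard_normal((n, 2))
    return ScenarioToy(x=x, color_label=color, shape_label=shape,
                       scenario=scenario, seed=seed)


@dataclass
class CohortConfig:
    """Generator configuration; defaults follow the study-population shape."""

    n: int = 10_000
    group_proportions: tuple[float, float, float] = (0.78, 0.15, 0.07)
    sex_ratio_by_group: tuple[float, float, float] = (0.40, 0.43, 0.49)
    age_mean_by_group: tuple[float, float, float] = (64.0, 61.0, 56.0)
    age_sd: float = 17.0
    prevalence_by_group: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "no_finding": (0.08, 0.09, 0.10),
            "condition_x": (0.41, 0.42, 0.33),
        }
    )
    n_filler_labels: int = 12
    filler_prevalence: float = 0.10
    encoding: str = "orthogonal"
    signal_strengths: dict[str, float] = field(
        default_factory=lambda: {
            "disease": 1.5,
            "group": 1.0,
            "sex": 1.0,
            "age": 0.5,
            "filler": 0.5,
        }
    )
    feature_dim: int = 64
    entangle_align: float = 0.8     # cos angle between group and disease axes
    age_disease_shift: float = 4.0  # years added for condition_x / subtracted for no_finding
    split_fractions: tuple[float, float, float] = (0.6, 0.1, 0.3)
    site: str = "site0"

    def validate(self) -> None:
        if self.n < 30:
            raise ValueError("cohort size n must be >= 30")
        if abs(sum(self.group_proportions) - 1.0) > 1e-6:
            raise ValueError("group_proportions must sum to 1")
        if self.encoding not in {"none", "orthogonal", "entangled"}:
            raise ValueError(f"unknown encoding {self.encoding!r}")
        nf = self.prevalence_by_group["no_finding"]
        cx = self.prevalence_by_group["condition_x"]
        for g, (a, b) in enumerate(zip(nf, cx)):
            if not (0 <= a <= 1 and 0 <= b <= 1):
                raise ValueError(f"prevalence out of [0,1] for group {GROUPS[g]}")
            if a + b > 1:
                raise ValueError(
                    f"infeasible prevalence pair for group {GROUPS[g]}: "
                    f"no_finding {a} + condition_x {b} > 1"
                )
        if abs(sum(self.split_fractions) - 1.0) > 1e-6:
            raise ValueError("split_fractions must sum to 1")
        if self.feature_dim < 5 + self.n_filler_labels:
            raise ValueError(
                "feature_dim must be at least 5 + n_filler_labels so every "
                "factor gets an orthogonal direction"
            )

    @property
    def label_names(self) -> list[str]:
        return list(FOCAL_LABELS) + [f"filler_{i}" for i in range(self.n_filler_labels)]


def composition_shift_config(n: int = 10_000) -> CohortConfig:
    """Cohort whose subgroup disparities are composition-driven by design.

    Group-dependent age (full 8-year spread between majority and minority
    group) drives operating-point shifts through the legitimate age-disease
    association, while the focal-label prevalence gaps are kept near-flat so
    the trained model has no exploitable group-prevalence shortcut, and the
    group attribute stays encoded orthogonally to the disease direction.
    Group sizes are moderately unbalanced so each group's operating point is
    measurable.  On this design, any residual subgroup disparity after
    balanced test-set resampling indicates model bias rather than test-set
    composition.
    """
    cfg = CohortConfig(n=n)
    cfg.group_proportions = (0.5, 0.3, 0.2)
    cfg.prevalence_by_group = {
        "no_finding": (0.085, 0.09, 0.095),
        "condition_x": (0.39, 0.40, 0.37),
    }
    return cfg


@dataclass
class Cohort:
    """Samples with attributes, 14 binary labels, and latent features/images."""

    data: pd.DataFrame                 # sample_id, split, site, group, sex, age + labels
    label_names: list[str]
    features: np.ndarray | None = None  # (n, feature_dim)
    images: np.ndarray | None = None    # (n, H, W) in [0, 1]
    config: CohortConfig | None = None

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def labels(self) -> np.ndarray:
        return self.data[self.label_names].to_numpy(dtype=int)

    def attr(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def subset(self, mask: np.ndarray) -> "Cohort":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return Cohort(
            data=self.data.iloc[idx].reset_index(drop=True),
            label_names=list(self.label_names),
            features=None if self.features is None else self.features[idx],
            images=None if self.images is None else self.images[idx],
            config=self.config,
        )

    def split(self, name: str) -> "Cohort":
        return self.subset(self.attr("split") == name)

    def disease_class(self) -> np.ndarray:
        """Overlay class: 'no_finding', 'condition_x' or 'other'."""
        nf = self.attr("no_finding").astype(bool)
        cx = self.attr("condition_x").astype(bool)
        out = np.full(self.n, "other", dtype=object)
        out[nf] = "no_finding"
        out[cx] = "condition_x"
        return out


def _factor_directions(cfg: CohortConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Orthonormal factor directions in latent space (QR of a Gaussian)."""
    n_dirs = 5 + cfg.n_filler_labels  # disease, sex, age, two group axes, fillers
    m = rng.standard_normal((cfg.feature_dim, n_dirs))
    q, _ = np.linalg.qr(m)
    dirs = {
        "disease": q[:, 0],
        "sex": q[:, 1],
        "age": q[:, 2],
        "group_a": q[:, 3],
        "group_b": q[:, 4],
    }
    for i in range(cfg.n_filler_labels):
        dirs[f"filler_{i}"] = q[:, 5 + i]
    if cfg.encoding == "entangled":
        a = cfg.entangle_align
        dirs["group_a"] = a * dirs["disease"] + np.sqrt(1 - a * a) * dirs["group_a"]
    return dirs


def make_cohort(cfg: CohortConfig, seed: int = 0) -> Cohort:
    """Sample a cohort per ``cfg``; deterministic given the seed."""
    cfg.validate()
    rng = np.random.default_rng(seed)
    n = cfg.n

    group_idx = rng.choice(3, size=n, p=np.asarray(cfg.group_proportions))
    female = rng.random(n) < np.asarray(cfg.sex_ratio_by_group)[group_idx]
    sex = np.where(female, "female", "male")

    # mutually exclusive focal labels via a per-group categorical draw
    p_nf = np.asarray(cfg.prevalence_by_group["no_finding"])[group_idx]
    p_cx = np.asarray(cfg.prevalence_by_group["condition_x"])[group_idx]
    u = rng.random(n)
    no_finding = (u < p_nf).astype(int)
    condition_x = ((u >= p_nf) & (u < p_nf + p_cx)).astype(int)
    fillers = (
        rng.random((n, cfg.n_filler_labels)) < cfg.filler_prevalence
    ).astype(int)

    # age: truncated Gaussian per group, shifted by disease status
    mu = np.asarray(cfg.age_mean_by_group)[group_idx] + cfg.age_disease_shift * (
        condition_x - no_finding
    )
    age = mu + cfg.age_sd * rng.standard_normal(n)
    # resample out-of-range draws (truncation to [18, 95])
    for _ in range(50):
        bad = (age < 18) | (age > 95)
        if not bad.any():
            break
        age[bad] = mu[bad] + cfg.age_sd * rng.standard_normal(int(bad.sum()))
    age = np.clip(age, 18, 95)

    dirs = _factor_directions(cfg, rng)
    s = cfg.signal_strengths
    z_disease = (condition_x - no_finding).astype(float)
    z_sex = np.where(female, 1.0, -1.0)
    z_age = (age - np.mean(cfg.age_mean_by_group)) / cfg.age_sd
    x = rng.standard_normal((n, cfg.feature_dim))
    x += s["disease"] * np.outer(z_disease, dirs["disease"])
    x += s["sex"] * np.outer(z_sex, dirs["sex"])
    x += s["age"] * np.outer(z_age, dirs["age"])
    if cfg.encoding != "none":
        gxy = _GROUP_SIMPLEX[group_idx]
        x += s["group"] * (
            np.outer(gxy[:, 0], dirs["group_a"]) + np.outer(gxy[:, 1], dirs["group_b"])
        )
    for i in range(cfg.n_filler_labels):
        x += s["filler"] * np.outer(2.0 * fillers[:, i] - 1.0, dirs[f"filler_{i}"])

    split = rng.choice(
        np.array(SPLITS, dtype=object), size=n, p=np.asarray(cfg.split_fractions)
    )

    data = pd.DataFrame(
        {
            "sample_id": [f"{cfg.site}-{i:06d}" for i in range(n)],
            "split": split,
            "site": cfg.site,
            "group": np.array(GROUPS, dtype=object)[group_idx],
            "sex": sex,
            "age": age,
            "no_finding": no_finding,
            "condition_x": condition_x,
        }
    )
    for i in range(cfg.n_filler_labels):
        data[f"filler_{i}"] = fillers[:, i]
    return Cohort(data=data, label_names=cfg.label_names, features=x, config=cfg)


def render_images(cohort: Cohort, size: int = 32, seed: int = 0) -> Cohort:
    """Render latent factors to a deterministic grayscale image stack.

    Factor-to-appearance map: disease status modulates a central blob, group
    membership sets the frequency of a sinusoidal border pattern, sex sets the
    orientation of a corner bar, and age modulates global brightness.
    """
    if cohort.features is None:
        raise ValueError("cohort has no features to render")
    if size < 16:
        raise ValueError("image size must be >= 16 pixels")
    cfg = cohort.config or CohortConfig()
    rng = np.random.default_rng(seed)
    n = cohort.n
    yy, xx = np.mgrid[0:size, 0:size] / (size - 1)
    r2 = (yy - 0.5) ** 2 + (xx - 0.5) ** 2
    blob = np.exp(-r2 / 0.04)
    group_idx = np.searchsorted(np.array(GROUPS), cohort.attr("group"))
    z_d = (cohort.attr("condition_x") - cohort.attr("no_finding")).astype(float)
    z_age = (cohort.attr("age") - 60.0) / 20.0
    female = cohort.attr("sex") == "female"
    s = cfg.signal_strengths

    imgs = np.empty((n, size, size), dtype=np.float64)
    freqs = np.array([2.0, 4.0, 6.0])
    bar = max(2, size // 10)
    for i in range(n):
        img = 0.35 + 0.08 * np.tanh(z_age[i]) * np.ones((size, size))
        img = img + 0.25 * np.tanh(s["disease"] * z_d[i]) * blob
        if cfg.encoding != "none" and s["group"] > 0:
            amp = 0.10 * min(s["group"], 1.5)
            img = img + amp * np.sin(2 * np.pi * freqs[group_idx[i]] * xx)
        if female[i]:
            img[:bar, : size // 2] += 0.15 * s["sex"]
        else:
            img[: size // 2, :bar] += 0.15 * s["sex"]
        imgs[i] = img
    imgs += 0.05 * rng.standard_normal((n, size, size))
    np.clip(imgs, 0.0, 1.0, out=imgs)
    return replace(cohort, images=imgs)


def summarize_population(cohort: Cohort) -> pd.DataFrame:
    """Population table: per split x group counts, sex, age, focal labels."""
    if cohort.n == 0:
        raise ValueError("cohort is empty")
    rows = []
    df = cohort.data
    for split in ("all",) + SPLITS:
        sub = df if split == "all" else df[df["split"] == split]
        total = len(sub)
        for group in ("all",) + GROUPS:
            g = sub if group == "all" else sub[sub["group"] == group]
            ng = len(g)
            empty = ng == 0
            rows.append(
                {
                    "split": split,
                    "group": group,
                    "n": ng,
                    "pct": 100.0 * ng / total if total else 0.0,
                    "female_n": int((g["sex"] == "female").sum()),
                    "female_pct": 100.0 * (g["sex"] == "female").mean() if ng else 0.0,
                    "age_mean": float(g["age"].mean()) if ng else 0.0,
                    "age_sd": float(g["age"].std(ddof=0)) if ng else 0.0,
                    "no_finding_n": int(g["no_finding"].sum()),
                    "no_finding_pct": 100.0 * g["no_finding"].mean() if ng else 0.0,
                    "condition_x_n": int(g["condition_x"].sum()),
                    "condition_x_pct": 100.0 * g["condition_x"].mean() if ng else 0.0,
                    "empty_group": empty,
                }
            )
    return pd.DataFrame(rows)


def save_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.data.to_csv(out / "cohort.csv", index=False)
    if cohort.features is not None:
        np.save(out / "features.npy", cohort.features)
    if cohort.images is not None:
        np.save(out / "images.npy", cohort.images)


def load_cohort(in_dir: str | Path) -> Cohort:
    src = Path(in_dir)
    data = pd.read_csv(src / "cohort.csv")
    base = ["sample_id", "split", "site", "group", "sex", "age"]
    label_names = [c for c in data.columns if c not in base]
    features = None
    images = None
    if (src / "features.npy").exists():
        features = np.load(src / "features.npy")
    if (src / "images.npy").exists():
        images = np.load(src / "images.npy")
    return Cohort(data=data, label_names=label_names, features=features, images=images)
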