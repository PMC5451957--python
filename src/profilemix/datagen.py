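"""Synthetic use-report scenarios with known ground truth.

Real pesticide-use analyses of this kind rest on confidential cohort and
geocoded residence data, so every downstream stage of this package is
exercised on simulated data with planted structure.  Two generators are
provided:

``generate_use_report_scenario``
    Emulates the full data-collection chain: a grid of one-square-mile
    sections, per-section application records (zero-inflated log-normal
    kilograms with a one-factor within-chemical-class copula), maternal
    residences placed so that subjects of the same latent cluster are
    spatially contiguous, pregnancy trimester windows, and a continuous
    FSIQ-scale outcome driven by the latent cluster plus confounders.

``generate_profiles_direct``
    Skips the GIS chain and draws quartile-categorised profiles directly
    from per-cluster categorical distributions — the clustering sampler's
    native input — for unit tests and parameter-recovery studies.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "DEFAULT_CLASS_MAP",
    "DEFAULT_CONFOUNDERS",
    "ScenarioConfig",
    "GroundTruth",
    "generate_use_report_scenario",
    "generate_profiles_direct",
    "recovery_category_probs",
    "fsiq_recovery_preset",
    "write_scenario",
]

#: The 15 actives retained in the motivating analysis, by chemical class:
#: seven organophosphates, two carbamates, four pyrethroids, one Mn-based
#: fungicide and one neonicotinoid.
DEFAULT_CLASS_MAP: dict[str, str] = {
    "oxydemeton-methyl": "OP",
    "acephate": "OP",
    "chlorpyrifos": "OP",
    "diazinon": "OP",
    "malathion": "OP",
    "dimethoate": "OP",
    "naled": "OP",
    "methomyl": "carbamate",
    "thiodicarb": "carbamate",
    "permethrin": "pyrethroid",
    "cypermethrin": "pyrethroid",
    "cyhalothrin": "pyrethroid",
    "esfenvalerate": "pyrethroid",
    "maneb": "Mn-fungicide",
    "imidacloprid": "neonicotinoid",
}

#: (name, kind, effect on the FSIQ-scale outcome). Mirrors the covariate set
#: used in cohort analyses of this design: home environment score, poverty,
#: child age/sex/test language, maternal education/intelligence/origin/
#: depression, and a log-scale urinary OP-metabolite biomarker.
DEFAULT_CONFOUNDERS: list[tuple[str, str, float]] = [
    ("home_score", "continuous", 1.5),
    ("household_poverty", "binary", -2.0),
    ("child_age", "continuous", 1.0),
    ("child_sex", "binary", 0.5),
    ("test_language", "binary", -1.0),
    ("maternal_education", "binary", 2.0),
    ("maternal_ppvt", "continuous", 2.5),
    ("maternal_origin", "binary", 1.0),
    ("maternal_depression", "binary", -1.5),
    ("log10_daps", "continuous", -1.0),
]

#: Per-pesticide probability that a section reports no use at all.  Higher
#: inflation for the actives whose population 25th percentile is zero in
#: real use-report summaries (naled, malathion, thiodicarb, cypermethrin,
#: esfenvalerate).
_DEFAULT_ZERO_INFLATION: dict[str, float] = {
    "naled": 0.75,
    "malathion": 0.6,
    "thiodicarb": 0.75,
    "cypermethrin": 0.75,
    "esfenvalerate": 0.6,
}

SECTION_SIDE_M = 1609.34  # one-square-mile section side


@dataclasses.dataclass
class ScenarioConfig:
    """Parameters of a simulated use-report scenario.

    The defaults describe a Salinas-Valley-like setting: 15 actives from 5
    chemical classes, strong within-class correlation, right-skewed
    zero-inflated section-level kilograms, three latent use patterns laid
    out in contiguous blocks of the section grid, and an IQ-scale outcome
    with cluster effects and a realistic confounded residual.
    """

    n_subjects: int = 120
    class_map: dict[str, str] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CLASS_MAP)
    )
    n_true_clusters: int = 3
    #: (n_true_clusters, P) positive multipliers on section-level kilograms;
    #: None -> uniform rows (0.15, 6.0, 2.0): a low-use, a very-high-use and
    #: a moderately-high-use pattern.
    cluster_use_multipliers: np.ndarray | None = None
    within_class_correlation: float = 0.8
    #: scalar or name -> probability; None -> per-pesticide defaults.
    zero_inflation: float | dict[str, float] | None = None
    outcome_effects: tuple[float, ...] = (0.0, -6.9, -6.4)
    confounder_spec: list[tuple[str, str, float]] = dataclasses.field(
        default_factory=lambda: list(DEFAULT_CONFOUNDERS)
    )
    outcome_mean: float = 100.0
    noise_sd: float = 10.0
    grid_shape: tuple[int, int] = (12, 8)
    section_side_m: float = SECTION_SIDE_M
    buffer_radius_m: float = 1000.0
    #: log-scale mean/sd of a single application event's kilograms
    log_kg_mean: float = 0.0
    log_kg_sd: float = 1.0
    event_noise_sd: float = 0.5
    applications_per_year: int = 26
    year: int = 2000
    seed: int = 0

    @property
    def pesticides(self) -> list[str]:
        return list(self.class_map)

    def resolved_multipliers(self) -> np.ndarray:
        P = len(self.class_map)
        if self.cluster_use_multipliers is not None:
            m = np.asarray(self.cluster_use_multipliers, dtype=float)
            if m.shape != (self.n_true_clusters, P):
                raise ValueError(
                    f"cluster_use_multipliers must have shape "
                    f"({self.n_true_clusters}, {P}), got {m.shape}"
                )
            if (m < 0).any():
                raise ValueError("cluster_use_multipliers must be >= 0")
            return m
        base = np.array([0.15, 6.0, 2.0, 0.5, 3.0, 1.0, 4.0, 0.3])
        levels = base[: self.n_true_clusters]
        if self.n_true_clusters > base.size:
            raise ValueError("supply cluster_use_multipliers for >8 clusters")
        return np.repeat(levels[:, None], P, axis=1)

    def resolved_zero_inflation(self) -> np.ndarray:
        if self.zero_inflation is None:
            zi = np.array(
                [_DEFAULT_ZERO_INFLATION.get(p, 0.3) for p in self.pesticides]
            )
        elif isinstance(self.zero_inflation, dict):
            zi = np.array(
                [self.zero_inflation.get(p, 0.3) for p in self.pesticides]
            )
        else:
            zi = np.full(len(self.class_map), float(self.zero_inflation))
        if ((zi < 0) | (zi > 1)).any():
            raise ValueError("zero_inflation must lie in [0, 1]")
        return zi

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.n_true_clusters <= 0:
            raise ValueError("n_true_clusters must be positive")
        if not (0.0 <= self.within_class_correlation < 1.0):
            raise ValueError("within_class_correlation must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if len(self.outcome_effects) != self.n_true_clusters:
            raise ValueError("one outcome effect per true cluster required")
        self.resolved_multipliers()
        self.resolved_zero_inflation()


@dataclasses.dataclass
class GroundTruth:
    """Planted structure stored alongside every generated dataset."""

    true_labels: np.ndarray  # (n,) cluster ids 1..n_true_clusters
    true_cluster_effects: dict[int, float]
    true_confounder_effects: dict[str, float]

    def __post_init__(self) -> None:
        self.true_labels = np.asarray(self.true_labels, dtype=int)
        k = len(self.true_cluster_effects)
        present = set(np.unique(self.true_labels))
        if not present <= set(range(1, k + 1)):
            raise ValueError("labels must lie in 1..n_true_clusters")


def _make_confounders(
    spec: list[tuple[str, str, float]], n: int, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray]:
    """Continuous confounders ~ N(0,1); binary ~ Bernoulli(0.5)."""
    cols, effects = {}, []
    for name, kind, effect in spec:
        if kind == "continuous":
            cols[name] = rng.normal(size=n)
        elif kind == "binary":
            cols[name] = rng.integers(0, 2, size=n).astype(float)
        else:
            raise ValueError(f"unknown confounder kind {kind!r}")
        effects.append(float(effect))
    return pd.DataFrame(cols, index=pd.RangeIndex(n)), np.array(effects)


def _outcome(
    labels: np.ndarray,
    cluster_effects: np.ndarray,
    W: pd.DataFrame,
    w_effects: np.ndarray,
    mean: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    y = mean + cluster_effects[labels - 1]
    if len(W.columns):
        y = y + W.to_numpy() @ w_effects
    return y + rng.normal(scale=noise_sd, size=labels.size)


def generate_use_report_scenario(config: ScenarioConfig):
    """Simulate application records, residences, pregnancies and outcomes.

    Returns ``(applications, residences, pregnancies, sections, outcome,
    truth)`` where the first three are DataFrames in the schemas consumed by
    :mod:`profilemix.exposure`, ``sections`` maps section id to its square's
    (xmin, ymin, xmax, ymax), ``outcome`` holds subject_id / fsiq /
    confounders, and ``truth`` is a :class:`GroundTruth`.

    Sections are assigned to latent clusters in contiguous vertical bands of
    the grid, and each subject's residence is placed inside their cluster's
    band, so cumulative use is spatially autocorrelated by construction.
    Within-class correlation between pesticides is induced by a shared
    per-section Gaussian factor per chemical class (one-factor copula); the
    same latent value drives both the zero-inflation threshold and the
    log-normal magnitude, so high-use sections are high for the whole class.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    pesticides = config.pesticides
    P = len(pesticides)
    classes = sorted(set(config.class_map.values()))
    class_idx = np.array(
        [classes.index(config.class_map[p]) for p in pesticides]
    )
    gx, gy = config.grid_shape
    side = config.section_side_m
    mult = config.resolved_multipliers()
    zi = config.resolved_zero_inflation()
    rho = config.within_class_correlation

    # --- sections and their latent cluster (contiguous column bands) ---
    band_w = gx / config.n_true_clusters
    sections: dict[str, tuple[float, float, float, float]] = {}
    section_cluster: dict[str, int] = {}
    ids = []
    for ix in range(gx):
        for iy in range(gy):
            sid = f"S{ix:02d}{iy:02d}"
            sections[sid] = (ix * side, iy * side, (ix + 1) * side, (iy + 1) * side)
            section_cluster[sid] = min(int(ix // band_w), config.n_true_clusters - 1) + 1
            ids.append(sid)

    # --- per-section latent factors and application records ---
    u_class = rng.normal(size=(len(ids), len(classes)))
    eps = rng.normal(size=(len(ids), P))
    g = np.sqrt(rho) * u_class[:, class_idx] + np.sqrt(1.0 - rho) * eps
    use_threshold = norm.ppf(zi)  # section uses pesticide iff g > threshold

    start = dt.date(config.year, 1, 1)
    n_ev = config.applications_per_year
    event_dates = [
        start + dt.timedelta(days=int(round(k * 365 / n_ev)))
        for k in range(n_ev)
    ]
    rows: list[tuple[str, str, str, float]] = []
    for si, sid in enumerate(ids):
        cl = section_cluster[sid]
        for pi, pest in enumerate(pesticides):
            if zi[pi] >= 1.0 or g[si, pi] <= use_threshold[pi]:
                continue
            base = config.log_kg_mean + config.log_kg_sd * g[si, pi]
            noise = rng.normal(scale=config.event_noise_sd, size=n_ev)
            kg = np.exp(base + noise) * mult[cl - 1, pi]
            for d, k in zip(event_dates, kg):
                rows.append((sid, d.isoformat(), pest, float(k)))
    applications = pd.DataFrame(
        rows, columns=["section_id", "date", "chemical", "kg"]
    )

    # --- subjects: labels, residences inside the cluster band, pregnancies ---
    labels = np.arange(config.n_subjects) % config.n_true_clusters + 1
    rng.shuffle(labels)
    radius = config.buffer_radius_m
    xmax, ymax = gx * side, gy * side
    xs = np.empty(config.n_subjects)
    ys = np.empty(config.n_subjects)
    for i, lab in enumerate(labels):
        lo = (lab - 1) * band_w * side
        hi = min(lab * band_w * side, xmax)
        lo, hi = max(lo, radius), min(hi, xmax - radius)
        if hi <= lo or ymax - radius <= radius:
            raise ValueError(
                f"grid too small: 1-km buffer around residences of cluster "
                f"{lab} cannot fit inside the section grid"
            )
        xs[i] = rng.uniform(lo, hi)
        ys[i] = rng.uniform(radius, ymax - radius)

    preg_len = (93, 93, 94)  # trimester lengths, days
    res_rows, preg_rows = [], []
    for i in range(config.n_subjects):
        sid = f"subj{i:04d}"
        conception = start + dt.timedelta(days=int(rng.integers(0, 365 - 280)))
        t0 = conception
        bounds = []
        for L in preg_len:
            t1 = t0 + dt.timedelta(days=L - 1)
            bounds.append((t0, t1))
            t0 = t1 + dt.timedelta(days=1)
        preg_rows.append(
            (sid, *(d.isoformat() for se in bounds for d in se))
        )
        res_rows.append(
            (
                sid,
                float(xs[i]),
                float(ys[i]),
                bounds[0][0].isoformat(),
                bounds[2][1].isoformat(),
            )
        )
    residences = pd.DataFrame(
        res_rows, columns=["subject_id", "x_m", "y_m", "start_date", "end_date"]
    )
    pregnancies = pd.DataFrame(
        preg_rows,
        columns=[
            "subject_id",
            "t1_start", "t1_end",
            "t2_start", "t2_end",
            "t3_start", "t3_end",
        ],
    )

    # --- outcome ---
    W, w_eff = _make_confounders(config.confounder_spec, config.n_subjects, rng)
    effects = np.asarray(config.outcome_effects, dtype=float)
    y = _outcome(labels, effects, W, w_eff, config.outcome_mean, config.noise_sd, rng)
    outcome = pd.concat(
        [
            pd.DataFrame(
                {"subject_id": residences["subject_id"], "fsiq": y}
            ),
            W,
        ],
        axis=1,
    )
    truth = GroundTruth(
        true_labels=labels,
        true_cluster_effects={c + 1: float(effects[c]) for c in range(effects.size)},
        true_confounder_effects={
            name: float(e) for (name, _, _), e in zip(config.confounder_spec, w_eff)
        },
    )
    return applications, residences, pregnancies, sections, outcome, truth


def generate_profiles_direct(
    n: int,
    P: int,
    K: int,
    partition: GroundTruth,
    category_probs: np.ndarray,
    seed: int,
    confounder_spec: list[tuple[str, str, float]] | None = None,
    outcome_mean: float = 100.0,
    noise_sd: float = 4.0,
    pesticide_names: list[str] | None = None,
):
    """Draw categorical profiles x_ip | cluster directly, plus an outcome.

    ``category_probs`` has shape (n_clusters, P, K); each probability vector
    must sum to 1 within 1e-12. Returns ``(profiles, outcome)`` DataFrames;
    profile entries lie in 1..K.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    probs = np.asarray(category_probs, dtype=float)
    n_clusters = len(partition.true_cluster_effects)
    if probs.shape != (n_clusters, P, K):
        raise ValueError(
            f"category_probs must have shape ({n_clusters}, {P}, {K})"
        )
    if np.abs(probs.sum(axis=2) - 1.0).max() > 1e-12:
        raise ValueError("each category probability vector must sum to 1")
    labels = partition.true_labels
    if labels.size != n:
        raise ValueError("partition labels must cover all n subjects")

    rng = np.random.default_rng(seed)
    # inverse-CDF draw, vectorised over subjects per pesticide
    x = np.empty((n, P), dtype=np.int64)
    u = rng.random(size=(n, P))
    for p in range(P):
        cdf = np.cumsum(probs[:, p, :], axis=1)  # (n_clusters, K)
        x[:, p] = 1 + (u[:, p, None] > cdf[labels - 1, :-1]).sum(axis=1)

    spec = confounder_spec if confounder_spec is not None else []
    W, w_eff = _make_confounders(spec, n, rng)
    effects = np.array(
        [partition.true_cluster_effects[c] for c in range(1, n_clusters + 1)]
    )
    y = _outcome(labels, effects, W, w_eff, outcome_mean, noise_sd, rng)

    names = pesticide_names or [f"pest{p + 1:02d}" for p in range(P)]
    subj = [f"subj{i:04d}" for i in range(n)]
    profiles = pd.DataFrame(x, columns=names, index=subj)
    outcome = pd.concat(
        [pd.DataFrame({"subject_id": subj, "fsiq": y}).set_index("subject_id"), W.set_index(profiles.index)],
        axis=1,
    ).reset_index(names="subject_id")
    return profiles, outcome


def recovery_category_probs(
    n_clusters: int = 3, P: int = 15, K: int = 4, peak: float = 0.7
) -> np.ndarray:
    """Per-cluster categorical distributions peaked on a signature quartile.

    Cluster 1 (the planted low-use reference) peaks on category 1; the
    remaining clusters peak on categories K, K-1, ... so profiles carry a
    clear joint-use signature while every category keeps positive mass.
    """
    rest = (1.0 - peak) / (K - 1)
    probs = np.full((n_clusters, P, K), rest)
    sig = [0] + [K - 1 - j for j in range(n_clusters - 1)]
    for c, k in enumerate(sig):
        probs[c, :, k] = peak
    return probs


def fsiq_recovery_preset(
    n: int = 300, seed: int = 0, P: int = 15, K: int = 4
):
    """Named preset: 3 clusters with FSIQ-scale effects (0, −6.9, −6.4).

    Balanced labels, 10 confounders from :data:`DEFAULT_CONFOUNDERS`, peaked
    category probabilities from :func:`recovery_category_probs`, residual
    noise sd 4.0 (small enough that estimation error, not noise, limits
    recovery of the planted deficits).  Returns ``(profiles, outcome,
    truth)``.
    """
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % 3 + 1
    rng.shuffle(labels)
    truth = GroundTruth(
        true_labels=labels,
        true_cluster_effects={1: 0.0, 2: -6.9, 3: -6.4},
        true_confounder_effects={
            name: eff for name, _, eff in DEFAULT_CONFOUNDERS
        },
    )
    profiles, outcome = generate_profiles_direct(
        n,
        P,
        K,
        truth,
        recovery_category_probs(3, P, K),
        seed=int(rng.integers(2**31)),
        confounder_spec=list(DEFAULT_CONFOUNDERS),
        noise_sd=4.0,
    )
    return profiles, outcome, truth


def write_scenario(
    outdir: str | Path,
    applications: pd.DataFrame,
    residences: pd.DataFrame,
    pregnancies: pd.DataFrame,
    sections: dict[str, tuple[float, float, float, float]],
    outcome: pd.DataFrame,
    truth: GroundTruth,
) -> dict[str, Path]:
    """Write the scenario as CSVs plus a planar-coordinate GeoJSON of sections."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in [
        ("applications", applications),
        ("residences", residences),
        ("pregnancies", pregnancies),
        ("outcome", outcome),
    ]:
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    gt = pd.DataFrame(
        {
            "subject_id": residences["subject_id"],
            "true_cluster": truth.true_labels,
        }
    )
    gt_path = outdir / "ground_truth.csv"
    gt.to_csv(gt_path, index=False)
    paths["ground_truth"] = gt_path

    features = []
    for sid, (x0, y0, x1, y1) in sections.items():
        ring = [[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]
        features.append(
            {
                "type": "Feature",
                "properties": {"section_id": sid},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    gj = {"type": "FeatureCollection", "features": features}
    gj_path = outdir / "sections.geojson"
    gj_path.write_text(json.dumps(gj))
    paths["sections"] = gj_path
    return paths


def read_sections_geojson(path: str | Path) -> dict[str, tuple[float, float, float, float]]:
    """Read the section bounding boxes back from the GeoJSON written above."""
    gj = json.loads(Path(path).read_text())
    out = {}
    for feat in gj["features"]:
        ring = np.asarray(feat["geometry"]["coordinates"][0], dtype=float)
        out[feat["properties"]["section_id"]] = (
            ring[:, 0].min(), ring[:, 1].min(), ring[:, 0].max(), ring[:, 1].max()
        )
    return out
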