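"""Synthetic data with planted ground truth for the full analysis chain.

Generates listener ratings, questionnaire item responses, and smooth 3D
contrast volumes whose statistical structure matches what the analysis
assumes: each speaker has a latent specificity skill ``s`` in [0, 1];
matched condition/scale ratings rise by ``effect_gain * s`` Likert
points over neutral, with likeable and hostile anti-structured and
intelligent orthogonal to both, so that the population rating
similarity matrix approaches the theoretical maximal-discrimination
matrix as s -> 1.  Questionnaire indices load on ``s`` through a latent
multivariate normal; volumes carry a planted linear dependence on the
centered modulation index.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` children, one per generator stage
(assignment/skill, ratings, reactivity, volumes), so every fixture is
reproducible and stages are independently stable under parameter
changes elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ratings import CONDITIONS, SOCIAL_TRAITS
from .voxel import VolumeSet, smooth_volume

#: Canonical index order for loadings and the intercorrelation matrix.
INDICES = ("cognitive_empathy", "affective_empathy", "machiavellianism", "psychopathy")

#: Default intercorrelations among the four indices
#: (Machiavellianism-psychopathy 0.60, all else 0).
DEFAULT_INTERCORR = np.array(
    [
        [1.0, 0.0, 0.0, 0.0],
        [0.0, 1.0, 0.0, 0.0],
        [0.0, 0.0, 1.0, 0.60],
        [0.0, 0.0, 0.60, 1.0],
    ]
)

#: Items per index and response categories for the two instruments.
ITEM_DESIGN = {
    "cognitive_empathy": ("QCAE", list(range(1, 20)), 4),
    "affective_empathy": ("QCAE", list(range(20, 32)), 4),
    "machiavellianism": ("SD3", list(range(1, 10)), 5),
    "narcissism": ("SD3", list(range(10, 19)), 5),
    "psychopathy": ("SD3", list(range(19, 28)), 5),
}

#: Mean rating shift (in units of effect_gain * s) for each
#: (condition, scale) pair.  Likeable and hostile recordings move each
#: other's scales in opposite directions; intelligent is orthogonal.
EFFECT = {
    ("likeable", "likeable"): 1.0,
    ("likeable", "hostile"): -1.0,
    ("hostile", "hostile"): 1.0,
    ("hostile", "likeable"): -1.0,
    ("intelligent", "intelligent"): 1.0,
}


class DesignError(ValueError):
    """The rating design is infeasible; the message names the violated count."""


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    n_speakers: int = 24
    n_listeners: int = 24
    speakers_per_listener: int = 10
    min_listeners_per_speaker: int = 10
    likert_min: int = 1
    likert_max: int = 7
    conditions: tuple[str, ...] = CONDITIONS
    scales: tuple[str, ...] = SOCIAL_TRAITS
    specificity_range: tuple[float, float] = (0.2, 1.0)
    effect_gain: float = 3.0
    baseline_mean: float = 4.0
    noise_sd: float = 1.0
    questionnaire_loadings: dict = field(
        default_factory=lambda: {
            "cognitive_empathy": 0.6,
            "affective_empathy": 0.0,
            "machiavellianism": 0.3,
            "psychopathy": 0.0,
        }
    )
    index_intercorrelations: np.ndarray = field(
        default_factory=lambda: DEFAULT_INTERCORR.copy()
    )
    item_loading: float = 0.5  # variance share of the index latent in each item
    male_fraction: float = 0.15
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    fwhm_mm: float = 8.0
    voxel_size_mm: float = 2.0
    beta_map_gain: float = 1.0
    volume_noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        slots = self.n_listeners * self.speakers_per_listener
        required = self.n_speakers * self.min_listeners_per_speaker
        if slots < required:
            raise DesignError(
                f"infeasible design: {self.n_listeners} listeners x "
                f"{self.speakers_per_listener} speakers each = {slots} slots < "
                f"{required} required ({self.n_speakers} speakers x "
                f"{self.min_listeners_per_speaker} listeners minimum)"
            )
        if self.speakers_per_listener > self.n_speakers:
            raise DesignError(
                f"speakers_per_listener ({self.speakers_per_listener}) exceeds "
                f"n_speakers ({self.n_speakers})"
            )
        if self.likert_min >= self.likert_max:
            raise ConfigError("likert_min must be below likert_max")
        lo, hi = self.specificity_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError("specificity_range must be within [0, 1]")
        C = np.asarray(self.index_intercorrelations, dtype=float)
        if C.shape != (len(INDICES), len(INDICES)):
            raise ConfigError("index_intercorrelations must be 4x4")
        if not np.allclose(C, C.T):
            raise ConfigError("index_intercorrelations must be symmetric")
        if np.linalg.eigvalsh(C).min() < -1e-8:
            raise ConfigError("index_intercorrelations must be positive semi-definite")
        for k, v in self.questionnaire_loadings.items():
            if k not in INDICES:
                raise ConfigError(f"unknown questionnaire index {k!r}")
            if not -1.0 <= v <= 1.0:
                raise ConfigError(f"loading for {k!r} outside [-1, 1]")
        if min(self.grid_shape) < 1:
            raise ConfigError("grid dimensions must be positive")
        if self.fwhm_mm < 0 or self.voxel_size_mm <= 0:
            raise ConfigError("fwhm must be >= 0 and voxel size > 0")


@dataclass
class GroundTruth:
    speaker_specificity: np.ndarray  # latent skill s per speaker
    assignment: dict  # listener_id -> tuple of speaker ids
    planted_voxel_beta_map: np.ndarray | None = None
    planted_betas: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "speaker_id": np.arange(len(self.speaker_specificity)),
                "specificity": self.speaker_specificity,
            }
        )


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    names = ("design", "ratings", "reactivity", "volumes", "performance")
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def assign_listeners(config: SimulationConfig, rng=None) -> dict[int, tuple[int, ...]]:
    """Balanced cyclic assignment of speaker subsets to listeners.

    A seeded permutation of speakers is walked cyclically; listener i
    takes the next ``speakers_per_listener`` distinct entries.  This
    covers every speaker floor(L*k/S) times or more, which meets the
    minimum-coverage requirement whenever the slot count does.
    Deterministic for a given config seed.
    """
    config.validate()
    if rng is None:
        rng = _stage_rngs(config.seed)["design"]
    perm = rng.permutation(config.n_speakers)
    assignment: dict[int, tuple[int, ...]] = {}
    c = 0
    for listener in range(config.n_listeners):
        block = [
            int(perm[(c + j) % config.n_speakers])
            for j in range(config.speakers_per_listener)
        ]
        assignment[listener] = tuple(block)
        c += config.speakers_per_listener
    counts = np.zeros(config.n_speakers, dtype=int)
    for block in assignment.values():
        counts[list(block)] += 1
    if counts.min() < config.min_listeners_per_speaker:
        raise DesignError(
            f"coverage shortfall: speaker {int(counts.argmin())} covered "
            f"{int(counts.min())} < {config.min_listeners_per_speaker} times"
        )
    return assignment


def make_ground_truth(config: SimulationConfig, rng=None) -> GroundTruth:
    config.validate()
    if rng is None:
        rng = _stage_rngs(config.seed)["design"]
    lo, hi = config.specificity_range
    s = rng.uniform(lo, hi, size=config.n_speakers)
    assignment = assign_listeners(config, rng)
    beta_map = default_beta_map(config.grid_shape, config.beta_map_gain)
    return GroundTruth(
        speaker_specificity=s,
        assignment=assignment,
        planted_voxel_beta_map=beta_map,
    )


def generate_ratings(
    config: SimulationConfig, ground_truth: GroundTruth, rng=None
) -> pd.DataFrame:
    """Long-format integer Likert ratings with the planted trait structure.

    One record per (listener, assigned speaker, condition, scale).  The
    latent rating is ``baseline + effect_gain * s * EFFECT[cond, scale]``
    plus Gaussian noise, rounded to the nearest integer and clipped to
    the Likert bounds.
    """
    config.validate()
    if rng is None:
        rng = _stage_rngs(config.seed)["ratings"]
    pairs = [
        (listener, speaker)
        for listener, block in ground_truth.assignment.items()
        for speaker in block
    ]
    listeners = np.repeat([p[0] for p in pairs], len(config.conditions) * len(config.scales))
    speakers = np.repeat([p[1] for p in pairs], len(config.conditions) * len(config.scales))
    cells = [(c, sc) for c in config.conditions for sc in config.scales]
    conds = np.tile([c for c, _ in cells], len(pairs))
    scls = np.tile([sc for _, sc in cells], len(pairs))
    eff = np.array([EFFECT.get(cell, 0.0) for cell in cells])
    eff_all = np.tile(eff, len(pairs))
    s = ground_truth.speaker_specificity[speakers]
    latent = config.baseline_mean + config.effect_gain * s * eff_all
    if config.noise_sd > 0:
        latent = latent + rng.normal(0.0, config.noise_sd, size=latent.shape)
    rating = np.clip(np.rint(latent), config.likert_min, config.likert_max).astype(int)
    return pd.DataFrame(
        {
            "listener_id": listeners,
            "speaker_id": speakers,
            "condition": conds,
            "scale": scls,
            "rating": rating,
        }
    )


def _latent_indices(
    config: SimulationConfig, s: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance index latents with the planted correlation structure.

    Builds the joint correlation matrix over [s*, indices] -- first
    row/column the loadings, index block the intercorrelations -- and
    draws the indices conditional on the realized (standardized) s.
    """
    lam = np.array([config.questionnaire_loadings.get(k, 0.0) for k in INDICES])
    C = np.asarray(config.index_intercorrelations, dtype=float)
    joint = np.empty((5, 5))
    joint[0, 0] = 1.0
    joint[0, 1:] = lam
    joint[1:, 0] = lam
    joint[1:, 1:] = C
    if np.linalg.eigvalsh(joint).min() < -1e-8:
        raise ConfigError(
            "loadings and index intercorrelations are jointly not positive "
            "semi-definite"
        )
    sd = s.std(ddof=0)
    zs = (s - s.mean()) / sd if sd > 0 else np.zeros_like(s)
    resid_cov = C - np.outer(lam, lam)
    w, V = np.linalg.eigh(resid_cov)
    B = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    e = rng.standard_normal((len(s), len(INDICES)))
    return zs[:, None] * lam[None, :] + e @ B.T


def generate_reactivity(
    config: SimulationConfig, ground_truth: GroundTruth, rng=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Item responses plus a speaker table (age, sex).

    Each index latent feeds its items through equal-weight loadings
    (``item_loading`` variance share), and item latents are thresholded
    into equal-width bins spanning [-2, 2] to give integer responses.
    Sum scores therefore always respect the instrument ranges.
    Narcissism items are generated as pure noise (they are validated but
    never analysed downstream).
    """
    config.validate()
    if rng is None:
        rng = _stage_rngs(config.seed)["reactivity"]
    n = config.n_speakers
    latents = _latent_indices(config, ground_truth.speaker_specificity, rng)
    latent_map = dict(zip(INDICES, latents.T))
    latent_map["narcissism"] = rng.standard_normal(n)

    w = np.sqrt(config.item_loading)
    frames = []
    for index, (instrument, items, ncat) in ITEM_DESIGN.items():
        z = latent_map[index]
        edges = np.linspace(-2.0, 2.0, ncat - 1)
        k = len(items)
        item_latent = w * z[None, :] + np.sqrt(1.0 - w**2) * rng.standard_normal((k, n))
        resp = np.digitize(item_latent, edges) + 1  # (items, speakers)
        frames.append(
            pd.DataFrame(
                {
                    "speaker_id": np.tile(np.arange(n), k),
                    "instrument": instrument,
                    "item": np.repeat(items, n),
                    "response": resp.reshape(-1),
                }
            )
        )
    items_df = (
        pd.concat(frames, ignore_index=True)
        .sort_values(["speaker_id", "instrument", "item"], kind="stable")
        .reset_index(drop=True)
    )

    n_male = int(np.clip(round(n * config.male_fraction), 1, n - 1))
    sex = np.array(["female"] * n, dtype=object)
    sex[rng.permutation(n)[:n_male]] = "male"
    age = np.clip(np.rint(rng.normal(21.0, 3.3, size=n)), 18, 45).astype(int)
    speakers_df = pd.DataFrame(
        {"speaker_id": np.arange(n), "age": age, "sex": sex}
    )
    return items_df, speakers_df


def generate_performance_from_betas(
    profiles: pd.DataFrame,
    betas: dict[str, float],
    noise_sd: float = 0.5,
    intercept: float = 0.75,
    seed: int = 0,
) -> pd.DataFrame:
    """Performance table with the modulation index planted directly.

    ``ed = intercept + sum_k betas[k] * z(index_k) + noise`` -- the
    direct recovery target for the association suite (the planted
    coefficients are on the z-scored predictor scale, matching the model
    that estimates them).  Delta-trait columns are filled with
    independent noise so the full suite can run.
    """
    rng = np.random.default_rng(seed)
    n = len(profiles)
    ed = np.full(n, float(intercept))
    for k, b in betas.items():
        x = profiles[k].to_numpy(dtype=float)
        ed = ed + b * (x - x.mean()) / x.std(ddof=1)
    ed = ed + rng.normal(0.0, noise_sd, size=n)
    out = pd.DataFrame({"speaker_id": profiles["speaker_id"].to_numpy(), "ed": ed})
    for col in ("delta_hostility", "delta_intelligence", "delta_likeability"):
        out[col] = rng.normal(1.0, 1.0, size=n)
    out["neutral_likeability"] = rng.normal(4.0, 0.5, size=n)
    return out


def default_beta_map(grid_shape, gain: float) -> np.ndarray:
    """Planted effect map: a central cube (side = dim//4) at ``gain``."""
    grid_shape = tuple(int(g) for g in grid_shape)
    beta = np.zeros(grid_shape)
    if gain != 0.0:
        slices = tuple(
            slice(d // 2 - max(1, d // 8), d // 2 + max(1, d // 8)) for d in grid_shape
        )
        beta[slices] = gain
    return beta


def generate_volumes(
    config: SimulationConfig,
    ground_truth: GroundTruth,
    ed_scores,
    rng=None,
) -> VolumeSet:
    """Per-speaker contrast volumes with a planted linear ED dependence.

    volume_i = beta_map * centered(ED_i) + noise, where the noise is
    white Gaussian smoothed to the configured FWHM and re-standardized
    to unit variance so the noise amplitude stays interpretable.
    """
    config.validate()
    if rng is None:
        rng = _stage_rngs(config.seed)["volumes"]
    ed = np.asarray(ed_scores, dtype=float)
    if ed.shape != (config.n_speakers,):
        raise ConfigError("need one ED score per speaker")
    beta_map = ground_truth.planted_voxel_beta_map
    if beta_map is None:
        beta_map = default_beta_map(config.grid_shape, config.beta_map_gain)
    ced = ed - ed.mean()
    data = np.empty((config.n_speakers,) + tuple(config.grid_shape))
    for i in range(config.n_speakers):
        noise = rng.standard_normal(config.grid_shape)
        noise = smooth_volume(noise, config.fwhm_mm, config.voxel_size_mm)
        noise = noise / noise.std()
        data[i] = beta_map * ced[i] + config.volume_noise_sd * noise
    shape = np.array(config.grid_shape)
    origin = -(shape - 1) / 2.0 * config.voxel_size_mm
    return VolumeSet(
        data=data, voxel_size_mm=config.voxel_size_mm, origin=origin
    )


@dataclass
class SimulationResult:
    config: SimulationConfig
    ground_truth: GroundTruth
    ratings: pd.DataFrame
    items: pd.DataFrame
    speakers: pd.DataFrame
    performance: pd.DataFrame
    volumes: VolumeSet | None


def simulate(config: SimulationConfig, include_volumes: bool = True) -> SimulationResult:
    """Full synthetic study: ratings, questionnaires, volumes.

    The volumes depend on the *realized* modulation index computed from
    the generated ratings, so every planted pathway is exercised
    end-to-end.
    """
    from .ratings import speaker_performance  # local import avoids cycle at module load

    config.validate()
    rngs = _stage_rngs(config.seed)
    gt = make_ground_truth(config, rngs["design"])
    ratings = generate_ratings(config, gt, rngs["ratings"])
    items, speakers = generate_reactivity(config, gt, rngs["reactivity"])
    performance = speaker_performance(ratings)
    volumes = None
    if include_volumes:
        perf = performance.set_index("speaker_id")["ed"]
        ed = perf.loc[np.arange(config.n_speakers)].to_numpy()
        volumes = generate_volumes(config, gt, ed, rngs["volumes"])
    return SimulationResult(
        config=config,
        ground_truth=gt,
        ratings=ratings,
        items=items,
        speakers=speakers,
        performance=performance,
        volumes=volumes,
    )
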