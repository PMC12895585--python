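"""Seeded synthetic cohorts with the structure the analysis assumes.

The study's recordings are not deposited, so every stage is exercised on
simulated data with planted, recoverable structure:

* Six ROI latents are band-limited (0.01-0.2 Hz) Gaussian processes
  mixed through a time-varying correlation matrix: a per-participant
  base matrix in Fisher-z space (group mean + participant offset +
  planted pathway effects + pair jitter) plus a slow sinusoidal
  modulation that makes window-wise FC genuinely dynamic.
* Channels replay their ROI latent through a forward optical model
  (functional dHbR = k * dHbO, systemic physiological sinusoids with
  dHbR = +1 * dHbO, modified Beer-Lambert forward, intensity =
  I0 * 10^-OD) plus white measurement noise and spike/step motion
  artifacts, with a clean 10-s baseline segment for QC.
* Clinical scores are planted with exact-in-expectation Spearman
  correlation to named features via a Gaussian copula on the cohort's
  realised (latent-trace) feature ranks.

Everything is reproducible bit-for-bit from (config, seed): participant
i draws from ``SeedSequence(seed, spawn_key=(i,))``.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .connectivity import pair_labels
from .montage import ROI_ORDER, Montage, load_default_montage
from .preprocess import RoiTimeSeries, bandpass, forward_mbll, load_default_extinction
from .recording import WAVELENGTHS_NM, RawRecording, TaskTimeline

GROUP_MDD = "MDD"
GROUP_HC = "HC"


@dataclass
class DynamicModulation:
    """Slow sinusoidal drift of pairwise coupling, in Fisher-z units."""

    amplitude_z: float = 0.1
    period_s: float = 60.0


@dataclass
class NoiseSpec:
    """Physiological and measurement noise, relative to unit latent SD."""

    cardiac_hz: float = 1.0
    cardiac_amp: float = 0.5
    respiratory_hz: float = 0.3
    respiratory_amp: float = 0.3
    mayer_hz: float = 0.1
    mayer_amp: float = 0.3
    white_sd: float = 0.3

    def components(self) -> list[tuple[float, float]]:
        return [
            (self.cardiac_hz, self.cardiac_amp),
            (self.respiratory_hz, self.respiratory_amp),
            (self.mayer_hz, self.mayer_amp),
        ]


@dataclass
class ArtifactSpec:
    """Motion artifacts: 1-sample spikes and persistent baseline steps."""

    spikes_per_min: float = 0.5
    shifts_per_min: float = 0.2
    spike_sd: float = 8.0
    shift_sd: float = 4.0


@dataclass
class ScoreSpec:
    mean: float
    sd: float
    lo: int
    hi: int


@dataclass
class ClinicalSpec:
    """Score distributions (MDD group) and planted feature links."""

    scores: dict[str, ScoreSpec] = field(
        default_factory=lambda: {
            "DASS-D": ScoreSpec(16.12, 1.93, 0, 21),
            "DASS-A": ScoreSpec(11.43, 4.16, 0, 21),
            "DASS-S": ScoreSpec(11.22, 5.77, 0, 21),
            "SHAPS": ScoreSpec(33.07, 7.37, 0, 42),
        }
    )
    #: (feature label, score name, target Spearman r)
    links: list[tuple[str, str, float]] = field(
        default_factory=lambda: [
            ("static|DLPFC(R)~mPFC(R)", "DASS-D", -0.48),
            ("static|DLPFC(R)~mPFC(R)", "DASS-A", -0.51),
            ("pc3|DLPFC(L)~TL(L)", "SHAPS", -0.52),
        ]
    )
    age_mean: float = 15.48
    age_sd: float = 1.71
    education_mean: float = 8.52
    education_sd: float = 1.84
    p_female: float = 0.55
    duration_mean_months: float = 10.0
    duration_sd_months: float = 6.0


@dataclass
class SimulationConfig:
    n_per_group: int = 80
    sampling_rate: float = 10.0
    timeline: TaskTimeline = field(default_factory=TaskTimeline)
    roi_names: tuple[str, ...] = ROI_ORDER
    group_mean_z: dict[str, float] = field(
        default_factory=lambda: {GROUP_HC: 0.39, GROUP_MDD: 0.32}
    )
    between_subject_sd_z: dict[str, float] = field(
        default_factory=lambda: {GROUP_HC: 0.07, GROUP_MDD: 0.11}
    )
    pair_jitter_sd_z: float = 0.04
    #: (pair label "A~B", group, additive Fisher-z offset)
    pathway_effects: list[tuple[str, str, float]] = field(
        default_factory=lambda: [
            ("DLPFC(R)~mPFC(R)", GROUP_MDD, -0.15),
            ("DLPFC(R)~TL(L)", GROUP_MDD, -0.15),
            ("DLPFC(L)~TL(L)", GROUP_MDD, -0.15),
            # elevation on top of the global group deficit (-0.07), so the
            # net group difference is comparable in magnitude to the
            # deficit pathways
            ("DLPFC(L)~TL(R)", GROUP_MDD, +0.22),
        ]
    )
    dynamic_modulation: DynamicModulation = field(default_factory=DynamicModulation)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec)
    clinical: ClinicalSpec = field(default_factory=ClinicalSpec)
    #: concentration scale of the unit-SD latent, in mM (1 uM)
    hemo_amplitude_mM: float = 1e-3
    #: forward-model hemodynamic ratios (match the preprocessing defaults)
    k_true: float = -0.6
    systemic_ratio_true: float = 1.0
    baseline_snr_db: float = 55.0
    low_snr_channels: tuple[int, ...] = (1, 10, 12, 20, 22, 31)
    low_snr_db: float = 35.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.roi_names) != 6:
            raise ValueError("exactly 6 ROI names required")
        if abs(self.timeline.analysis_s - 150.0) > 1e-9:
            raise ValueError("timeline must total 150 s of analysed period")
        for g, z in self.group_mean_z.items():
            if not np.isfinite(z) or abs(math.tanh(z)) >= 1 - 1e-9:
                raise ValueError(f"group mean z {z} for {g} implies |r| >= 1")
        for spec_amp in (
            self.dynamic_modulation.amplitude_z,
            self.noise.cardiac_amp,
            self.noise.respiratory_amp,
            self.noise.mayer_amp,
            self.noise.white_sd,
            self.artifacts.spikes_per_min,
            self.artifacts.shifts_per_min,
            self.pair_jitter_sd_z,
        ):
            if spec_amp < 0:
                raise ValueError("amplitudes and rates must be non-negative")
        for _, _, r in self.clinical.links:
            if abs(r) >= 1:
                raise ValueError(f"target Spearman r {r} out of (-1, 1)")

    # -- cohort layout ---------------------------------------------------

    @property
    def n_total(self) -> int:
        return 2 * self.n_per_group

    def group_of(self, index: int) -> str:
        if not 0 <= index < self.n_total:
            raise IndexError(f"participant index {index} out of range")
        return GROUP_MDD if index < self.n_per_group else GROUP_HC

    def participant_id(self, index: int) -> str:
        g = self.group_of(index)
        k = index + 1 if g == GROUP_MDD else index - self.n_per_group + 1
        return f"sub-{g}-{k:03d}"

    def n_task_samples(self) -> int:
        return int(round(self.timeline.analysis_s * self.sampling_rate))

    def rng_for(self, index: int, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(index, stream))
        )


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    recordings: list[RawRecording]
    roi_latents: list[RoiTimeSeries]
    clinical: pd.DataFrame
    truth: dict


# ---------------------------------------------------------------------------
# latent ROI traces


def _pair_index_map(roi_names: Sequence[str]) -> dict[str, tuple[int, int]]:
    idx = {r: i for i, r in enumerate(roi_names)}
    out = {}
    for lab in pair_labels(tuple(roi_names)):
        a, b = lab.split("~")
        out[lab] = (idx[a], idx[b])
    return out


def _band_limited_orthogonal_sources(
    rng: np.random.Generator,
    n_samples: int,
    sampling_rate: float,
    low_hz: float,
    high_hz: float,
    n_sources: int = 6,
) -> np.ndarray:
    """Unit-variance band-limited sources on disjoint Fourier combs.

    A 150-s record in the 0.01-0.2 Hz band carries only a handful of
    effective degrees of freedom, so sample correlations of generic
    band-limited noise wander far (SD ~ 0.4) from their population
    value and would swamp any planted structure.  Building each source
    from a disjoint, interleaved comb of Fourier modes (random Rayleigh
    amplitude and uniform phase per mode) makes the sources *exactly*
    orthogonal in-sample, so mixed traces realise the planted
    correlation matrix; and because sinusoids are near-eigenfunctions
    of any zero-phase filter, the orthogonality — hence the planted FC
    — survives the band-pass filtering of the analysis pipeline.
    Interleaving spreads every source evenly over the band so common
    filters rescale all sources almost equally.
    """
    freqs = np.fft.rfftfreq(n_samples, 1.0 / sampling_rate)
    band_bins = np.flatnonzero((freqs >= low_hz) & (freqs <= high_hz))
    if band_bins.size < n_sources:
        raise ValueError("record too short for the requested band")
    sources = np.empty((n_sources, n_samples))
    for i in range(n_sources):
        bins = band_bins[i::n_sources]
        spec = np.zeros(freqs.size, dtype=complex)
        amp = rng.rayleigh(1.0, size=bins.size)
        phase = rng.uniform(0, 2 * np.pi, size=bins.size)
        spec[bins] = amp * np.exp(1j * phase)
        s = np.fft.irfft(spec, n=n_samples)
        sources[i] = s / s.std()
    return sources


def participant_z_matrix(
    config: SimulationConfig, index: int, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Per-participant base Fisher-z matrix and the shared offset delta."""
    group = config.group_of(index)
    delta = rng.normal(0.0, config.between_subject_sd_z[group])
    z = np.full((6, 6), config.group_mean_z[group] + delta)
    pmap = _pair_index_map(config.roi_names)
    iu = np.triu_indices(6, 1)
    jitter = rng.normal(0.0, config.pair_jitter_sd_z, size=iu[0].size)
    z[iu] += jitter
    for pair, grp, off in config.pathway_effects:
        if grp == group:
            i, j = pmap[pair]
            z[min(i, j), max(i, j)] += off
    z[(iu[1], iu[0])] = z[iu]  # symmetrise
    np.fill_diagonal(z, np.inf)  # r = 1 on the diagonal
    return z, float(delta)


def _correlation_stack(z_base: np.ndarray, modulation: np.ndarray) -> np.ndarray:
    """R(t) from base z plus per-pair modulation; clipped to valid PSD."""
    T = modulation.shape[-1]
    iu = np.triu_indices(6, 1)
    z_t = np.repeat(z_base[None, iu[0], iu[1]], T, axis=0) + modulation.T  # T x 15
    r_t = np.tanh(z_t)
    R = np.empty((T, 6, 6))
    R[:] = np.eye(6)
    R[:, iu[0], iu[1]] = r_t
    R[:, iu[1], iu[0]] = r_t
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        # rare with defaults: project to the PSD cone by eigenvalue clipping
        w, V = np.linalg.eigh(R)
        w = np.clip(w, 1e-8, None)
        R = V @ (w[..., None] * np.swapaxes(V, -1, -2))
        d = np.sqrt(np.einsum("tii->ti", R))
        R = R / (d[:, :, None] * d[:, None, :])
        L = np.linalg.cholesky(R)
    return L


def generate_roi_latents(
    config: SimulationConfig, index: int
) -> tuple[np.ndarray, dict]:
    """Six latent ROI traces (6 x T, unit SD) plus the planted truth.

    Pairwise correlations of the band-limited latents have expectation
    tanh(z_base) per pair; with nonzero dynamic modulation the
    instantaneous coupling drifts sinusoidally at the configured period.
    """
    rng = config.rng_for(index, stream=0)
    T = config.n_task_samples()
    z_base, delta = participant_z_matrix(config, index, rng)

    mod = config.dynamic_modulation
    t = np.arange(T) / config.sampling_rate
    phases = rng.uniform(0, 2 * np.pi, size=15)
    if mod.amplitude_z > 0:
        modulation = mod.amplitude_z * np.sin(
            2 * np.pi * t[None, :] / mod.period_s + phases[:, None]
        )
    else:
        modulation = np.zeros((15, T))

    sources = _band_limited_orthogonal_sources(
        rng, T, config.sampling_rate, low_hz=0.01, high_hz=0.2
    )

    L = _correlation_stack(z_base, modulation)
    traces = np.einsum("tij,jt->it", L, sources)
    traces /= traces.std(axis=1, keepdims=True)

    truth = {
        "group": config.group_of(index),
        "delta_z": delta,
        "z_base_pairs": z_base[np.triu_indices(6, 1)].tolist(),
        "modulation_phases": phases.tolist(),
    }
    return traces, truth


# ---------------------------------------------------------------------------
# channel projection


def project_to_channels(
    latents: np.ndarray,
    montage: Montage,
    config: SimulationConfig,
    index: int,
) -> RawRecording:
    """Forward-model the ROI latents into a dual-wavelength raw recording.

    Each channel carries its ROI latent (functional component, with
    dHbR = k_true * dHbO), channel-specific physiological sinusoids
    (systemic component, dHbR = systemic_ratio * dHbO), white
    measurement noise, and Poisson-injected spike/step artifacts at the
    optical-density level; a clean 10-s baseline segment is prepended.
    """
    rng = config.rng_for(index, stream=1)
    roi_row = {r: i for i, r in enumerate(config.roi_names)}
    n_ch = montage.n_channels
    T = latents.shape[1]
    t = np.arange(T) / config.sampling_rate
    amp = config.hemo_amplitude_mM

    func = np.empty((n_ch, T))
    for c, ch in enumerate(montage.channels):
        roi = montage.roi_map[ch.id]
        if roi not in roi_row:
            raise ValueError(f"channel {ch.id} maps to unknown ROI {roi!r}")
        func[c] = latents[roi_row[roi]]
    func = amp * func

    systemic = np.zeros((n_ch, T))
    for f_hz, a in config.noise.components():
        if a <= 0:
            continue
        ph = rng.uniform(0, 2 * np.pi, size=n_ch)
        systemic += a * np.sin(2 * np.pi * f_hz * t[None, :] + ph[:, None])
    systemic = amp * systemic

    white = amp * config.noise.white_sd
    dHbO = func + systemic + rng.normal(0.0, white, size=(n_ch, T)) if white > 0 else func + systemic
    dHbR = config.k_true * func + config.systemic_ratio_true * systemic
    if white > 0:
        dHbR = dHbR + rng.normal(0.0, white, size=(n_ch, T))

    od = forward_mbll(
        dHbO,
        dHbR,
        dpf={lam: 6.0 for lam in WAVELENGTHS_NM},
        extinction=load_default_extinction(),
        distance_cm=montage.interoptode_distance_cm,
    )

    # motion artifacts: same onset and sign at both wavelengths
    log: list[dict] = []
    art = config.artifacts
    minutes = T / config.sampling_rate / 60.0
    for kind, rate, scale in (
        ("spike", art.spikes_per_min, art.spike_sd),
        ("shift", art.shifts_per_min, art.shift_sd),
    ):
        n_events = rng.poisson(rate * minutes)
        for _ in range(n_events):
            ch = int(rng.integers(0, n_ch))
            onset = int(rng.integers(0, T))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            for lam in WAVELENGTHS_NM:
                sd = od[lam][ch].std()
                if kind == "spike":
                    od[lam][ch, onset] += sign * scale * sd
                else:
                    od[lam][ch, onset:] += sign * scale * sd
            log.append(
                {
                    "type": kind,
                    "channel": montage.channels[ch].id,
                    "time_s": onset / config.sampling_rate,
                    "sign": sign,
                }
            )

    n_base = int(round(config.timeline.baseline_s * config.sampling_rate))
    snr = np.full(n_ch, config.baseline_snr_db)
    for i, ch in enumerate(montage.channels):
        if ch.id in config.low_snr_channels:
            snr[i] = config.low_snr_db
    sigma_rel = 10.0 ** (-snr / 20.0)
    i0 = 1.0
    intensity = {}
    for lam in WAVELENGTHS_NM:
        base = i0 * (1.0 + rng.normal(0.0, 1.0, size=(n_ch, n_base)) * sigma_rel[:, None])
        task = i0 * 10.0 ** (-od[lam])
        intensity[lam] = np.concatenate([base, task], axis=1)

    return RawRecording(
        participant_id=config.participant_id(index),
        intensity=intensity,
        channel_ids=list(montage.channel_ids),
        sampling_rate=config.sampling_rate,
        baseline_samples=n_base,
        timeline=config.timeline,
        group=config.group_of(index),
        log=log,
    )


# ---------------------------------------------------------------------------
# clinical table


def spearman_to_pearson_rho(r_s: float) -> float:
    """Gaussian-copula Pearson rho giving Spearman r_s: 2 sin(pi r_s / 6)."""
    return 2.0 * math.sin(math.pi * r_s / 6.0)


def generate_clinical(
    config: SimulationConfig, planted_features: pd.DataFrame, seed: int
) -> pd.DataFrame:
    """Clinical table with copula-planted feature-score correlations.

    ``planted_features`` is the cohort feature table (one row per
    participant, the 15 + 15N feature columns) against whose ranks the
    configured Spearman links are planted, MDD group only.  Scores are
    integers within instrument ranges; HC rows carry no scores,
    duration or medication, as in the source cohort design.
    """
    for feat, score, _ in config.clinical.links:
        if feat not in planted_features.columns:
            raise ValueError(
                f"clinical link feature {feat!r} not among the "
                f"{planted_features.shape[1]} feature labels"
            )
        if score not in config.clinical.scores:
            raise ValueError(f"unknown score {score!r}")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(999_983,)))
    spec = config.clinical
    rows = []
    ids = [config.participant_id(i) for i in range(config.n_total)]
    groups = [config.group_of(i) for i in range(config.n_total)]
    mdd_mask = np.array([g == GROUP_MDD for g in groups])
    mdd_ids = [pid for pid, m in zip(ids, mdd_mask) if m]

    # normal scores of the MDD participants' planted feature ranks
    links_by_score: dict[str, tuple[str, float]] = {}
    for feat, score, r in spec.links:
        links_by_score[score] = (feat, r)
    normal_scores: dict[str, np.ndarray] = {}
    for score, (feat, r) in links_by_score.items():
        vals = planted_features.loc[mdd_ids, feat].to_numpy(float)
        ranks = pd.Series(vals).rank(method="average").to_numpy()
        normal_scores[score] = sps_norm_ppf((ranks - 0.5) / ranks.size)

    n_mdd = len(mdd_ids)
    latents: dict[str, np.ndarray] = {}
    for score in spec.scores:
        eps = rng.standard_normal(n_mdd)
        if score in links_by_score:
            _, r = links_by_score[score]
            rho = spearman_to_pearson_rho(r)
            latents[score] = rho * normal_scores[score] + math.sqrt(1 - rho**2) * eps
        else:
            latents[score] = eps

    drugs = sorted(
        ("fluoxetine", "sertraline", "paroxetine", "clomipramine", "venlafaxine")
    )
    equivalents = {"fluoxetine": 40.0, "sertraline": 98.5, "paroxetine": 34.0,
                   "clomipramine": 116.1, "venlafaxine": 149.4}
    mdd_i = 0
    for pid, group in zip(ids, groups):
        age = float(np.clip(rng.normal(spec.age_mean, spec.age_sd), 12.0, 18.0))
        sex = "F" if rng.random() < spec.p_female else "M"
        edu = float(np.clip(rng.normal(spec.education_mean, spec.education_sd), 1.0, 13.0))
        row = {
            "participant_id": pid,
            "group": group,
            "age": round(age, 1),
            "sex": sex,
            "education_years": round(edu, 1),
            "duration_months": np.nan,
            "dass_d": np.nan,
            "dass_a": np.nan,
            "dass_s": np.nan,
            "shaps": np.nan,
            "medication": None,
            "dose_mg_day": np.nan,
        }
        if group == GROUP_MDD:
            for score, sc in spec.scores.items():
                val = sc.mean + sc.sd * latents[score][mdd_i]
                col = {"DASS-D": "dass_d", "DASS-A": "dass_a",
                       "DASS-S": "dass_s", "SHAPS": "shaps"}[score]
                row[col] = int(np.clip(round(val), sc.lo, sc.hi))
            row["duration_months"] = float(
                np.clip(rng.normal(spec.duration_mean_months, spec.duration_sd_months), 1.0, 48.0)
            )
            drug = drugs[int(rng.integers(0, len(drugs)))]
            dose = equivalents[drug] * rng.uniform(0.25, 1.25)
            row["medication"] = drug
            row["dose_mg_day"] = float(5 * round(dose / 5))
            mdd_i += 1
        rows.append(row)
    return pd.DataFrame(rows).set_index("participant_id")


def sps_norm_ppf(q: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    return norm.ppf(q)


# ---------------------------------------------------------------------------
# cohort assembly


def iter_recordings(
    config: SimulationConfig, montage: Montage | None = None
) -> Iterator[tuple[RawRecording, RoiTimeSeries, dict]]:
    """Yield (recording, latent ROI series, truth) per participant.

    Streaming companion of :func:`simulate_cohort` for large cohorts:
    recordings can be consumed and discarded one at a time.
    """
    montage = montage or load_default_montage()
    for i in range(config.n_total):
        latents, truth = generate_roi_latents(config, i)
        rec = project_to_channels(latents, montage, config, i)
        roi_ts = RoiTimeSeries(
            traces=latents,
            roi_order=tuple(config.roi_names),
            sampling_rate=config.sampling_rate,
            participant_id=config.participant_id(i),
            group=config.group_of(i),
        )
        truth = dict(truth, artifacts=rec.log)
        yield rec, roi_ts, truth


def latent_feature_table(
    config: SimulationConfig, roi_latents: Sequence[RoiTimeSeries]
):
    """Feature table computed from the noiseless latent ROI traces."""
    from .features import extract_features

    return extract_features(list(roi_latents))


def simulate_cohort(
    config: SimulationConfig, montage: Montage | None = None
) -> SyntheticCohort:
    """Full in-memory cohort: recordings, clinical table and truth."""
    montage = montage or load_default_montage()
    recordings: list[RawRecording] = []
    roi_latents: list[RoiTimeSeries] = []
    per_participant: dict[str, dict] = {}
    for rec, roi_ts, truth in iter_recordings(config, montage):
        recordings.append(rec)
        roi_latents.append(roi_ts)
        per_participant[rec.participant_id] = truth
    planted = latent_feature_table(config, roi_latents)
    clinical = generate_clinical(config, planted.table, config.seed)
    truth = {
        "seed": config.seed,
        "n_per_group": config.n_per_group,
        "group_mean_z": dict(config.group_mean_z),
        "pathway_effects": [list(e) for e in config.pathway_effects],
        "clinical_links": [list(l) for l in config.clinical.links],
        "n_components_latent": planted.n_components,
        "participants": per_participant,
        "planted_features": planted.table.to_dict(orient="index"),
    }
    return SyntheticCohort(
        config=config,
        recordings=recordings,
        roi_latents=roi_latents,
        clinical=clinical,
        truth=truth,
    )
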