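"""Synthetic experience-sampling fMRI with a known latent mind-wandering state.

The generator emulates the dense-sampling paradigm used throughout the
package: ~8-minute fixation runs at TR = 1.06 s, thought probes at uniform
45-90 s intervals, task-focus responses on a 1-8 Likert scale that are
reverse-coded downstream (plus a "9 = distracted" option), and BOLD signal in
which a slow latent attentional state drives both regional activation
amplitude (a default-network-like block) and the coupling of specific planted
region pairs.

Model
-----
* Latent state: a stationary unit-variance Ornstein-Uhlenbeck process with
  time constant ``latent_tau`` (lag-1 autocorrelation exp(-TR/tau)).
* Neural signal per region: white noise + activation_coupling * state, plus,
  for each planted edge (i, j), a shared white source loaded onto both
  endpoints with a state-dependent gain (logistic in the state; increasing
  for positive edges, decreasing for negative edges). This yields trial-window
  correlation differences of the kind connectome-based models assume.
* Hemodynamics: the neural signal is convolved with a canonical double-gamma
  HRF (peak 6 s, undershoot 16 s, ratio 1/6) and superimposed on a constant
  baseline as a ~1% fluctuation, plus white measurement noise.
* Ratings: the raw probe response is a clipped, rounded linear read-out of the
  latent state averaged over the 28 frames before the probe, optionally
  contaminated by motion and time-on-task confounds, and replaced by "9"
  (distracted) with probability ``p_distracted``.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .atlas import Atlas, block_atlas, SEVEN_NETWORKS
from .connectivity import n_edges, probe_frame, upper_triangle_pairs

__all__ = [
    "SimConfig",
    "GroundTruth",
    "ConfigurationError",
    "double_gamma_hrf",
    "simulate_latent_state",
    "simulate_run",
    "simulate_dataset",
    "generate_dataset",
    "planted_edge_config",
    "activation_config",
]

CONTENT_FLAGS = ("content_visual", "content_auditory", "content_emotional")
#: probability of each content flag on a mind-wandering trial
CONTENT_PROBS = (0.55, 0.35, 0.25)
#: steepness of the logistic mapping from latent state to planted-edge
#: loading; 2.0 gives a ~7x loading ratio between state +1 and -1 SD, i.e.
#: clearly separable window correlations at unit gain
EDGE_LOADING_SLOPE = 2.0


class ConfigurationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Data-generating configuration.

    Defaults mirror the acquisition they emulate: 300 cortical regions over 7
    networks, 8-minute runs at TR 1.06 s, probes every 45-90 s.
    """

    n_regions: int = 300
    network_labels: tuple[str, ...] | None = None  # default: 7 contiguous blocks
    n_runs: int = 46
    run_length: float = 480.0
    tr: float = 1.06
    probe_interval: tuple[float, float] = (45.0, 90.0)
    latent_tau: float = 30.0
    activation_coupling: tuple[float, ...] | None = None  # per-region, default 0
    planted_pos_edges: tuple[int, ...] = ()
    planted_neg_edges: tuple[int, ...] = ()
    edge_gain: float = 1.0
    rating_scale: float = 2.5
    rating_noise_sd: float = 1.0
    p_distracted: float = 0.1
    confound_gains: tuple[float, float] = (0.0, 0.0)  # (motion, time-on-task)
    baseline: float = 1000.0
    signal_pct: float = 1.0  # percent BOLD fluctuation per unit neural signal
    noise_sd: float = 1.0  # measurement noise, same units as neural signal
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_regions < 2:
            raise ConfigurationError("n_regions must be >= 2")
        if not (0 < self.tr < self.run_length):
            raise ConfigurationError("need 0 < tr < run_length")
        lo, hi = self.probe_interval
        if not lo < hi:
            raise ConfigurationError("probe interval min must be < max")
        if self.latent_tau <= 0:
            raise ConfigurationError("latent_tau must be positive")
        if not 0 <= self.p_distracted < 1:
            raise ConfigurationError("p_distracted must lie in [0, 1)")
        E = n_edges(self.n_regions)
        pos, neg = set(self.planted_pos_edges), set(self.planted_neg_edges)
        if pos & neg:
            raise ConfigurationError("planted positive/negative edge sets overlap")
        for e in pos | neg:
            if not 0 <= e < E:
                raise ConfigurationError(f"edge id {e} invalid for {self.n_regions} regions")
        if self.network_labels is not None and len(self.network_labels) != self.n_regions:
            raise ConfigurationError("network_labels length must equal n_regions")
        if self.activation_coupling is not None and len(self.activation_coupling) != self.n_regions:
            raise ConfigurationError("activation_coupling length must equal n_regions")

    @property
    def n_frames(self) -> int:
        return int(round(self.run_length / self.tr))

    def atlas(self) -> Atlas:
        if self.network_labels is None:
            return block_atlas(self.n_regions, SEVEN_NETWORKS, name="sim-7net")
        return Atlas(tuple(self.network_labels), name="sim-custom")

    def coupling_vector(self) -> np.ndarray:
        if self.activation_coupling is None:
            return np.zeros(self.n_regions)
        return np.asarray(self.activation_coupling, dtype=float)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("network_labels", "activation_coupling", "planted_pos_edges",
                    "planted_neg_edges", "probe_interval", "confound_gains"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("planted_pos_edges", "planted_neg_edges"):
            d[key] = tuple(d.get(key) or ())
        for key in ("probe_interval", "confound_gains"):
            d[key] = tuple(d[key])
        if d.get("network_labels") is not None:
            d["network_labels"] = tuple(d["network_labels"])
        if d.get("activation_coupling") is not None:
            d["activation_coupling"] = tuple(d["activation_coupling"])
        return cls(**d)


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery tests."""

    latent_state: np.ndarray  # concatenated across runs
    planted_pos_edges: tuple[int, ...]
    planted_neg_edges: tuple[int, ...]
    activation_coupling: np.ndarray
    true_rating_signal: np.ndarray  # per retained probe: pre-probe state mean

    def to_dict(self) -> dict:
        return {
            "latent_state": self.latent_state.tolist(),
            "planted_pos_edges": list(self.planted_pos_edges),
            "planted_neg_edges": list(self.planted_neg_edges),
            "activation_coupling": self.activation_coupling.tolist(),
            "true_rating_signal": self.true_rating_signal.tolist(),
        }


def double_gamma_hrf(tr: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at TR, peak normalised to 1.

    Peak at 6 s, undershoot at 16 s, undershoot ratio 1/6.
    """
    from scipy.stats import gamma as gamma_dist

    t = np.arange(0, duration, tr)
    peak = gamma_dist(6, scale=1.0).pdf(t)
    under = gamma_dist(16, scale=1.0).pdf(t)
    h = peak - under / 6.0
    return h / h.max()


def simulate_latent_state(config: SimConfig, n_frames: int, rng: np.random.Generator) -> np.ndarray:
    """Stationary zero-mean unit-variance OU series at the frame grid.

    Discrete AR(1): s[t] = phi * s[t-1] + sqrt(1 - phi^2) * eps, with
    phi = exp(-tr / latent_tau), so the lag-1 autocorrelation is phi.
    """
    if config.latent_tau <= 0:
        raise ConfigurationError("latent_tau must be positive")
    phi = float(np.exp(-config.tr / config.latent_tau))
    innov_sd = float(np.sqrt(max(0.0, 1.0 - phi * phi)))
    eps = rng.standard_normal(n_frames)
    s = np.empty(n_frames)
    s[0] = eps[0]
    for t in range(1, n_frames):
        s[t] = phi * s[t - 1] + innov_sd * eps[t]
    return s


def _draw_probe_onsets(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.probe_interval
    onsets = []
    t = rng.uniform(lo, hi)  # first probe also 45-90 s from run start
    while t < config.run_length - config.tr:
        onsets.append(t)
        t += rng.uniform(lo, hi)
    return np.asarray(onsets)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_run(
    config: SimConfig,
    run_index: int,
    rng: np.random.Generator,
    rating_window_frames: int = 28,
):
    """Simulate one run.

    Returns (bold, events, state) where ``bold`` is the region x frame raw
    signal matrix, ``events`` a BIDS-style trial table for the run, and
    ``state`` the latent series. Probes whose pre-probe rating window does not
    fit within the run are not emitted.
    """
    F = config.n_frames
    R = config.n_regions
    s = simulate_latent_state(config, F, rng)

    neural = rng.standard_normal((R, F))
    neural += config.coupling_vector()[:, None] * s[None, :]
    h = double_gamma_hrf(config.tr)
    # unit-L2 kernel: convolution shapes the autocorrelation without
    # inflating variance, so gains are in units of baseline BOLD SD
    h = h / np.sqrt((h * h).sum())
    conv = fftconvolve(neural, h[None, :], axes=1)[:, :F]

    # shared edge sources enter at the haemodynamic level (frame-wise white
    # sources with state-dependent loading): the planted quantity is the
    # within-window correlation itself, which HRF smoothing of the source
    # would only blur without changing the planted contrast
    iu, ju = upper_triangle_pairs(R)
    pos_load = config.edge_gain * _logistic(EDGE_LOADING_SLOPE * s)
    neg_load = config.edge_gain * _logistic(-EDGE_LOADING_SLOPE * s)
    for e in config.planted_pos_edges:
        src = pos_load * rng.standard_normal(F)
        conv[iu[e]] += src
        conv[ju[e]] += src
    for e in config.planted_neg_edges:
        src = neg_load * rng.standard_normal(F)
        conv[iu[e]] += src
        conv[ju[e]] += src

    meas = config.noise_sd * rng.standard_normal((R, F))
    bold = config.baseline * (1.0 + (config.signal_pct / 100.0) * (conv + meas))

    onsets = _draw_probe_onsets(config, rng)
    records = []
    for k, onset in enumerate(onsets):
        p = probe_frame(onset, config.tr)
        if p < rating_window_frames or p > F:
            continue
        m = float(s[p - rating_window_frames : p].mean())
        fd = float(rng.lognormal(mean=np.log(0.1), sigma=0.4))
        time_frac = onset / config.run_length
        g_motion, g_time = config.confound_gains
        # the raw response is task focus: high latent mind-wandering state
        # means a LOW raw response; reverse-coding (9 - raw) downstream then
        # recovers a rating that increases with the latent state
        raw = (
            4.5
            - config.rating_scale * m
            - config.rating_noise_sd * rng.standard_normal()
            - g_motion * (fd - 0.1) / 0.1
            - g_time * (time_frac - 0.5) * 2.0
        )
        response_raw = int(np.clip(np.round(raw), 1, 8))
        distracted = bool(rng.random() < config.p_distracted)
        if distracted:
            response_raw = 9
        rec = {
            "onset": float(onset),
            "duration": 0.0,
            "response_raw": response_raw,
            "fd_mean": fd,
            "run_id": f"run-{run_index:02d}",
            "true_state_mean": m,
        }
        is_mw = (not distracted) and (9 - response_raw >= 5)
        for flag, prob in zip(CONTENT_FLAGS, CONTENT_PROBS):
            rec[flag] = int(rng.random() < prob) if is_mw else 0
        records.append(rec)
    if not records:
        warnings.warn(f"run {run_index}: too short for any probe", stacklevel=2)
    events = pd.DataFrame.from_records(
        records,
        columns=["onset", "duration", "response_raw", "fd_mean", "run_id",
                 "true_state_mean", *CONTENT_FLAGS],
    )
    return bold, events, s


def simulate_dataset(config: SimConfig):
    """Simulate all runs of one synthetic subject.

    Returns (runs, events, ground_truth, atlas): ``runs`` maps run_id to the
    raw region x frame matrix; ``events`` is the concatenated trial table with
    session ids (5 sessions by default split, mirroring the paradigm).
    """
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_runs)
    runs: dict[str, np.ndarray] = {}
    frames = []
    states = []
    n_sessions = 5
    per_session = int(np.ceil(config.n_runs / n_sessions))
    for r in range(config.n_runs):
        rng = np.random.default_rng(children[r])
        bold, events, s = simulate_run(config, r, rng)
        run_id = f"run-{r:02d}"
        events["session_id"] = f"ses-{r // per_session + 1:02d}"
        runs[run_id] = bold
        frames.append(events)
        states.append(s)
    events = pd.concat(frames, ignore_index=True)
    gt = GroundTruth(
        latent_state=np.concatenate(states),
        planted_pos_edges=tuple(config.planted_pos_edges),
        planted_neg_edges=tuple(config.planted_neg_edges),
        activation_coupling=config.coupling_vector(),
        true_rating_signal=events["true_state_mean"].to_numpy(),
    )
    return runs, events, gt, config.atlas()


# ---------------------------------------------------------------------------
# on-disk dataset


def _write_matrix_tsv(path: Path, data: np.ndarray, compress: bool) -> None:
    header = "\t".join(str(k) for k in range(data.shape[1]))
    body = "\n".join("\t".join(f"{v:.6f}" for v in row) for row in data)
    text = header + "\n" + body + "\n"
    if compress:
        # mtime pinned so identical seeds give byte-identical files
        with gzip.GzipFile(path, "wb", mtime=0) as fh:
            fh.write(text.encode())
    else:
        path.write_text(text)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def generate_dataset(config: SimConfig, out_dir, overwrite: bool = False, compress: bool = False) -> dict:
    """Write a complete synthetic dataset to ``out_dir``.

    Per-run matrix TSVs, BIDS-style events TSVs, the atlas table, a
    ground-truth JSON and a manifest JSON with checksums. Output is
    byte-identical for identical (config, seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True to replace")

    runs, events, gt, atlas = simulate_dataset(config)
    ext = ".tsv.gz" if compress else ".tsv"
    files: dict[str, str] = {}
    for run_id, data in runs.items():
        mpath = out / f"{run_id}_bold{ext}"
        _write_matrix_tsv(mpath, data, compress)
        files[mpath.name] = _sha256(mpath)
        ev = events[events["run_id"] == run_id].drop(columns=["true_state_mean"])
        epath = out / f"{run_id}_events.tsv"
        ev.to_csv(epath, sep="\t", index=False, na_rep="n/a", float_format="%.6f")
        files[epath.name] = _sha256(epath)
    apath = out / "atlas.tsv"
    atlas.to_tsv(apath)
    files[apath.name] = _sha256(apath)
    gpath = out / "ground_truth.json"
    gpath.write_text(json.dumps(gt.to_dict()))
    files[gpath.name] = _sha256(gpath)
    cpath = out / "config.json"
    cpath.write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True))
    files[cpath.name] = _sha256(cpath)
    manifest = {
        "tr": config.tr,
        "n_runs": config.n_runs,
        "n_regions": config.n_regions,
        "seed": config.seed,
        "files": dict(sorted(files.items())),
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# study-condition factories


def planted_edge_config(
    n_regions: int = 50,
    n_runs: int = 18,
    n_pos: int = 40,
    n_neg: int = 40,
    edge_gain: float = 1.5,
    rating_noise_sd: float = 0.25,
    seed: int = 0,
    edge_seed: int | None = None,
    within_network: str | None = None,
    network_labels: tuple[str, ...] | None = None,
    exclude_edges=(),
    **kwargs,
) -> SimConfig:
    """A configuration with randomly planted positive/negative edge sets.

    ``within_network`` restricts planted edges to pairs whose *both* endpoints
    lie in the named network (used by lesion-specificity studies);
    ``edge_seed`` decouples the planted-edge draw from the noise seed so two
    subjects can share or not share edges independently of their noise;
    ``exclude_edges`` removes edge ids from the candidate pool (to plant sets
    strictly disjoint from another subject's).
    """
    rng = np.random.default_rng(seed if edge_seed is None else edge_seed)
    atlas = (
        Atlas(tuple(network_labels)) if network_labels is not None
        else block_atlas(n_regions, SEVEN_NETWORKS)
    )
    iu, ju = upper_triangle_pairs(n_regions)
    if within_network is not None:
        members = set(atlas.regions_of(within_network).tolist())
        candidates = np.flatnonzero(
            [i in members and j in members for i, j in zip(iu, ju)]
        )
    else:
        candidates = np.arange(len(iu))
    if len(exclude_edges):
        candidates = np.setdiff1d(candidates, np.asarray(list(exclude_edges)))
    if len(candidates) < n_pos + n_neg:
        raise ConfigurationError("not enough candidate edges for the planted sets")
    chosen = rng.choice(candidates, size=n_pos + n_neg, replace=False)
    return SimConfig(
        n_regions=n_regions,
        network_labels=tuple(atlas.labels) if network_labels is not None else None,
        n_runs=n_runs,
        planted_pos_edges=tuple(int(e) for e in chosen[:n_pos]),
        planted_neg_edges=tuple(int(e) for e in chosen[n_pos:]),
        edge_gain=edge_gain,
        rating_noise_sd=rating_noise_sd,
        p_distracted=kwargs.pop("p_distracted", 0.0),
        seed=seed,
        **kwargs,
    )


def activation_config(
    n_regions: int = 50,
    n_runs: int = 12,
    network: str = "Default",
    gain: float = 1.0,
    rating_noise_sd: float = 0.5,
    seed: int = 0,
    **kwargs,
) -> SimConfig:
    """A configuration with activation coupling confined to one network."""
    atlas = block_atlas(n_regions, SEVEN_NETWORKS)
    coupling = np.zeros(n_regions)
    coupling[atlas.regions_of(network)] = gain
    return SimConfig(
        n_regions=n_regions,
        n_runs=n_runs,
        activation_coupling=tuple(coupling),
        rating_noise_sd=rating_noise_sd,
        p_distracted=kwargs.pop("p_distracted", 0.0),
        seed=seed,
        **kwargs,
    )
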