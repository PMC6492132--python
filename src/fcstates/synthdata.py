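"""Synthetic multi-subject, multi-state functional-connectivity data.

Generates node-by-time series for a study design of K steady-state conditions
("states") scanned in S subjects, with ground-truth connectivity exported for
recovery tests.  The generative model places state effects in *precision*
(inverse-covariance) space — i.e. on direct connections — which is what makes
the comparison between full and partial correlation downstream meaningful:
full correlation mixes direct and indirect dependencies, partial correlation
targets the direct ones.

Per (state, band) a sparse, diagonally dominant precision matrix is built from
a base support shared by all states plus state-and-band-specific edge
perturbations.  Each sample sums band-limited multivariate Gaussian series
(one per band, filtered after mixing so that the target correlation structure
is preserved exactly), scales node standard deviations by a state-specific
amplitude vector, and adds white measurement noise.

Randomness is split by a fixed rule — ``SeedSequence([seed, stream, *index])``
— so that adding subjects or states never perturbs existing samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .spectral import FilterSpec, filter_series

# stream ids for the fixed seed-splitting rule
_STREAM_BASE = 0
_STREAM_STATE_FX = 1
_STREAM_AMP = 2
_STREAM_SUBJECT = 3
_STREAM_SAMPLE = 4
_STREAM_MAPS = 5

_SPD_EIG_FLOOR = 1e-8
_SPD_MAX_RETRIES = 50


def _rng(seed: int, stream: int, *index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream), *map(int, index)]))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and effect-size parameters of the simulator.

    Defaults mirror the emulated design: 15 subjects x 5 states, 230
    timepoints at TR = 1.3 s (~5 min steady-state scans), 75 samples total.

    Parameters
    ----------
    bands : tuple of (low_hz, high_hz)
        Frequency bands carrying coupling structure; each must lie within
        (0, Nyquist].  Default is the classic slow FC band (0.01, 0.1) Hz.
    band_effects : tuple of float or None
        Per-band multiplier on ``edge_effect`` (None = 1 for every band);
        lets state effects be confined to specific bands.
    base_density : float
        Fraction of off-diagonal precision entries in the shared base support.
    edge_effect : float
        Magnitude of state-specific perturbations of precision entries
        (direct-edge effects).
    amp_effect : float
        Per-state node-standard-deviation scaling in [0, 1); state amplitude
        vectors are 1 + amp_effect * u with u in {-1, 0, +1} per node.
    subject_sd : float
        Scale of the subject's multiplicative edge-strength factors
        (constant across states within a subject).
    global_signal_sd : float
        Scale of a scan-varying global signal added uniformly to all nodes:
        a state-independent shared-variance nuisance (the classic fMRI global
        confound) that inflates marginal correlations but is conditioned away
        by partial correlation.  Each scan draws its own amplitude in
        [0.5, 1.5] x this scale.
    noise_sd : float
        Standard deviation of additive white measurement noise.
    """

    n_subjects: int = 15
    n_states: int = 5
    n_nodes: int = 10
    n_timepoints: int = 230
    sampling_interval: float = 1.3
    bands: tuple[tuple[float, float], ...] = ((0.01, 0.1),)
    band_effects: tuple[float, ...] | None = None
    base_density: float = 0.5
    edge_effect: float = 0.6
    amp_effect: float = 0.2
    subject_sd: float = 0.3
    global_signal_sd: float = 2.0
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_nodes < 1 or self.n_timepoints < 1:
            raise ValueError("n_subjects, n_nodes, n_timepoints must be positive")
        if self.n_states < 2:
            raise ValueError("need at least 2 states")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        nyq = self.nyquist
        bands = tuple((float(lo), float(hi)) for lo, hi in self.bands)
        object.__setattr__(self, "bands", bands)
        for lo, hi in bands:
            if not (0 < lo < hi <= nyq):
                raise ValueError(f"band ({lo}, {hi}) Hz outside (0, Nyquist={nyq:.6g}]")
        if self.band_effects is not None:
            be = tuple(float(b) for b in self.band_effects)
            if len(be) != len(bands):
                raise ValueError("band_effects length must match bands")
            if any(b < 0 for b in be):
                raise ValueError("band_effects must be >= 0")
            object.__setattr__(self, "band_effects", be)
        if not 0 < self.base_density <= 1:
            raise ValueError("base_density must be in (0, 1]")
        if min(self.edge_effect, self.subject_sd, self.noise_sd, self.global_signal_sd) < 0:
            raise ValueError("effect and noise scales must be >= 0")
        if not 0 <= self.amp_effect < 1:
            raise ValueError("amp_effect must be in [0, 1) to keep amplitudes positive")
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")

    @property
    def nyquist(self) -> float:
        return 0.5 / self.sampling_interval

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.sampling_interval

    def band_effect(self, band: int) -> float:
        if self.band_effects is None:
            return 1.0
        return self.band_effects[band]


@dataclass(frozen=True)
class GroundTruth:
    """Exported generative targets for recovery tests.

    ``precisions[(state, band)]`` is the state-level SPD precision matrix
    (without subject effects); ``supports[(state, band)]`` its off-diagonal
    nonzero pattern as a frozenset of (i, j) pairs with i < j;
    ``amplitudes[state]`` the positive node-s.d. scale vector.
    """

    precisions: Mapping[tuple[int, int], np.ndarray]
    supports: Mapping[tuple[int, int], frozenset]
    amplitudes: Mapping[int, np.ndarray]

    def covariance(self, state: int, band: int = 0) -> np.ndarray:
        return np.linalg.inv(self.precisions[(state, band)])


@dataclass
class StudyDataset:
    """Per-(subject, state) node-by-time series with sampling metadata."""

    samples: dict[tuple[int, int], np.ndarray]
    sampling_interval: float
    provenance: SimulationConfig | str | None = None

    @property
    def subjects(self) -> list[int]:
        return sorted({s for s, _ in self.samples})

    @property
    def states(self) -> list[int]:
        return sorted({k for _, k in self.samples})

    @property
    def n_nodes(self) -> int:
        return next(iter(self.samples.values())).shape[0]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def validate(self) -> None:
        n = self.n_nodes
        for key, ts in self.samples.items():
            if ts.shape[0] != n:
                raise ValueError(f"sample {key} has {ts.shape[0]} nodes, expected {n}")
        expected = {(s, k) for s in self.subjects for k in self.states}
        if set(self.samples) != expected:
            raise ValueError("samples do not form a complete subject x state design")


def _pair_index(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n_nodes, k=1)


#: probability that a base precision off-diagonal is negative (negative
#: precision entries give positive partial/full correlations; resting FC is
#: predominantly positive)
_NEGATIVE_SIGN_PROB = 0.9

#: fraction of support edges modulated by each state
_STATE_EDGE_FRACTION = 0.3


def _base_offdiag(config: SimulationConfig) -> np.ndarray:
    """Shared base support values on the upper-triangle pair vector."""
    rows, _ = _pair_index(config.n_nodes)
    n_pairs = rows.size
    rng = _rng(config.seed, _STREAM_BASE)
    mask = rng.random(n_pairs) < config.base_density
    if not mask.any():
        mask[0] = True  # degenerate tiny configs: keep at least one edge
    signs = np.where(rng.random(n_pairs) < _NEGATIVE_SIGN_PROB, -1.0, 1.0)
    vals = rng.uniform(0.3, 0.6, n_pairs) * signs
    return np.where(mask, vals, 0.0)


def _state_offdiag(config: SimulationConfig, state: int, band: int) -> np.ndarray:
    """Base support with state-and-band-specific multiplicative edge modulation.

    A designated subset of support edges is scaled by 1 +/- edge_effect
    (sign-preserving for edge_effect < 1): states modulate the strength of
    direct connections rather than creating sign flips, mirroring task
    modulation of coupling on top of a stable connectome.
    """
    off = _base_offdiag(config).copy()
    support = np.flatnonzero(off)
    rng = _rng(config.seed, _STREAM_STATE_FX, state, band)
    m = max(1, int(round(_STATE_EDGE_FRACTION * support.size)))
    idx = rng.choice(support, size=min(m, support.size), replace=False)
    signs = rng.choice([-1.0, 1.0], idx.size)
    off[idx] *= 1.0 + signs * config.edge_effect * config.band_effect(band)
    return off


def _assemble_precision(off: np.ndarray, n_nodes: int) -> np.ndarray:
    """Symmetric precision from the pair vector, strong-coupling diagonal.

    The diagonal is set below strict dominance (0.3 + 0.6 * row sum of
    |off-diagonals|) so that couplings are strong and marginal correlations
    mix many direct edges — the regime where full and partial correlation
    genuinely differ; positive definiteness is enforced afterwards by
    diagonal loading.
    """
    rows, cols = _pair_index(n_nodes)
    p = np.zeros((n_nodes, n_nodes))
    p[rows, cols] = off
    p += p.T
    np.fill_diagonal(p, 0.3 + 0.6 * np.abs(p).sum(axis=1))
    return p


def _ensure_spd(p: np.ndarray) -> np.ndarray:
    """Diagonal loading (x1.1 per retry, max 50) until smallest eigenvalue > 0."""
    p = p.copy()
    for _ in range(_SPD_MAX_RETRIES):
        if np.linalg.eigvalsh(p)[0] > _SPD_EIG_FLOOR:
            return p
        p[np.diag_indices_from(p)] *= 1.1
    raise np.linalg.LinAlgError(
        "could not reach a positive-definite precision after maximum diagonal "
        "loading; the configuration is pathological"
    )


def make_state_precision(config: SimulationConfig, state: int, band: int = 0) -> np.ndarray:
    """State-level SPD precision matrix for one frequency band.

    Base support (shared by all states) at ``base_density`` plus a state- and
    band-specific perturbation of magnitude ``edge_effect`` on a designated
    edge subset; SPD is enforced by diagonal loading.  With
    ``edge_effect = 0`` all states share one precision per band.
    """
    if not 0 <= state < config.n_states:
        raise ValueError(f"state {state} out of range")
    if not 0 <= band < len(config.bands):
        raise ValueError(f"band {band} out of range")
    off = _state_offdiag(config, state, band)
    return _ensure_spd(_assemble_precision(off, config.n_nodes))


def _subject_precision(config: SimulationConfig, subject: int, state: int, band: int) -> np.ndarray:
    """State precision with the subject's multiplicative edge-strength factors.

    Each subject carries a per-edge factor 1 + subject_sd * N(0, 1), constant
    across states; a subject's whole connectome is stronger or weaker edge by
    edge, which is exactly the nuisance the within-subject ratio
    normalization downstream is designed to cancel.
    """
    off = _state_offdiag(config, state, band)
    srng = _rng(config.seed, _STREAM_SUBJECT, subject, band)
    dev = srng.normal(0.0, 1.0, off.size)  # drawn for all pairs: stable stream layout
    off = off * (1.0 + config.subject_sd * dev)
    return _ensure_spd(_assemble_precision(off, config.n_nodes))


def _state_amplitude(config: SimulationConfig, state: int) -> np.ndarray:
    rng = _rng(config.seed, _STREAM_AMP, state)
    u = rng.choice([-1.0, 0.0, 1.0], config.n_nodes)
    return 1.0 + config.amp_effect * u


def simulate_band_limited_series(
    cov: np.ndarray,
    band: tuple[float, float],
    n_timepoints: int,
    sampling_interval: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Band-limited multivariate Gaussian series with target covariance ``cov``.

    Draws i.i.d. multivariate normal vectors (Cholesky mixing of unit-variance
    streams) and applies the same zero-phase band-pass to every channel, which
    preserves the cross-channel correlation structure exactly; the variance is
    scaled down by the band's zero-phase power fraction (see
    :func:`fcstates.spectral.band_power_fraction`).  Output is zero-mean per
    node.
    """
    cov = np.asarray(cov, dtype=float)
    nyq = 0.5 / sampling_interval
    low, high = float(band[0]), float(band[1])
    if not 0 < low < high <= nyq:
        raise ValueError(f"band ({low}, {high}) Hz outside (0, Nyquist={nyq:.6g}]")
    # a top edge at (or within 1% of) Nyquist is clipped for filter design
    if high > 0.999 * nyq:
        high = 0.999 * nyq
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal((cov.shape[0], n_timepoints))
    x = chol @ z
    spec = FilterSpec("bandpass", (low, high), 1.0 / sampling_interval)
    x = filter_series(x, spec)
    return x - x.mean(axis=1, keepdims=True)


def simulate_dataset(config: SimulationConfig) -> tuple[StudyDataset, GroundTruth]:
    """Simulate the full study: one node-by-time matrix per (subject, state).

    Fully reproducible from ``config.seed``; per-(subject, state) random
    streams are independent, so enlarging the design leaves existing samples
    bit-identical.
    """
    n_bands = len(config.bands)
    rows, cols = _pair_index(config.n_nodes)

    precisions: dict[tuple[int, int], np.ndarray] = {}
    supports: dict[tuple[int, int], frozenset] = {}
    for state in range(config.n_states):
        for band in range(n_bands):
            p = make_state_precision(config, state, band)
            precisions[(state, band)] = p
            off = p[rows, cols]
            supports[(state, band)] = frozenset(
                (int(i), int(j)) for i, j, v in zip(rows, cols, off) if v != 0.0
            )
    amplitudes = {s: _state_amplitude(config, s) for s in range(config.n_states)}

    samples: dict[tuple[int, int], np.ndarray] = {}
    for subject in range(config.n_subjects):
        for state in range(config.n_states):
            rng = _rng(config.seed, _STREAM_SAMPLE, subject, state)
            ts = np.zeros((config.n_nodes, config.n_timepoints))
            for band_idx, band in enumerate(config.bands):
                p_sub = _subject_precision(config, subject, state, band_idx)
                cov = np.linalg.inv(p_sub)
                ts += simulate_band_limited_series(
                    cov, band, config.n_timepoints, config.sampling_interval, rng
                )
            ts *= amplitudes[state][:, None]
            if config.global_signal_sd > 0:
                amp = config.global_signal_sd * (0.5 + rng.random())
                ts = ts + amp * rng.standard_normal(config.n_timepoints)[None, :]
            if config.noise_sd > 0:
                ts = ts + rng.normal(0.0, config.noise_sd, ts.shape)
            ts -= ts.mean(axis=1, keepdims=True)
            samples[(subject, state)] = ts

    dataset = StudyDataset(samples, config.sampling_interval, provenance=config)
    truth = GroundTruth(precisions, supports, amplitudes)
    return dataset, truth


# ---------------------------------------------------------------------------
# voxel-level forward model (for testing the extraction stage)
# ---------------------------------------------------------------------------


def make_spatial_maps(
    n_voxels: int,
    n_nodes: int,
    overlap: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic parcellation: hard labels plus overlapping weight maps.

    Returns ``(maps, labels)``: a voxel-by-node weight matrix (unit-norm
    columns; the hard-partition indicator blended with ``overlap``-weighted
    spill into the neighbouring parcels) and a 1-based hard label vector with
    every parcel non-empty.  ``overlap = 0`` gives column-orthogonal maps.
    """
    if n_voxels < n_nodes:
        raise ValueError(f"n_voxels={n_voxels} < n_nodes={n_nodes}")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    blocks = np.array_split(np.arange(n_voxels), n_nodes)
    labels = np.empty(n_voxels, dtype=int)
    for k, block in enumerate(blocks):
        labels[block] = k + 1
    perm = rng.permutation(n_voxels)
    labels = labels[perm]
    maps = np.zeros((n_voxels, n_nodes))
    maps[np.arange(n_voxels), labels - 1] = 1.0
    if overlap > 0:
        for nb in (-1, 1):
            neighbour = labels - 1 + nb
            ok = (neighbour >= 0) & (neighbour < n_nodes)
            maps[np.arange(n_voxels)[ok], neighbour[ok]] += overlap
    maps /= np.linalg.norm(maps, axis=0, keepdims=True)
    return maps, labels


def simulate_voxel_data(
    node_series: np.ndarray,
    maps: np.ndarray,
    voxel_noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Forward model: voxel-by-time = maps @ node_series + white noise."""
    node_series = np.asarray(node_series, dtype=float)
    maps = np.asarray(maps, dtype=float)
    if maps.shape[1] != node_series.shape[0]:
        raise ValueError(
            f"maps have {maps.shape[1]} nodes but series has {node_series.shape[0]}"
        )
    if voxel_noise_sd < 0:
        raise ValueError("voxel_noise_sd must be >= 0")
    out = maps @ node_series
    if voxel_noise_sd > 0:
        out = out + rng.normal(0.0, voxel_noise_sd, out.shape)
    return out


# ---------------------------------------------------------------------------
# on-disk representation (delimited text + manifest)
# ---------------------------------------------------------------------------


def write_dataset(dataset: StudyDataset, out_dir: str | Path) -> Path:
    """Write one TSV per (subject, state) plus a manifest table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for (subject, state), ts in sorted(dataset.samples.items()):
        name = f"sub{subject:03d}_state{state:02d}.tsv"
        np.savetxt(out_dir / name, ts, delimiter="\t")
        records.append({"subject": subject, "state": state, "path": name,
                        "tr": dataset.sampling_interval})
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(records).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_dataset(manifest: str | Path) -> StudyDataset:
    """Load a dataset from a manifest written by :func:`write_dataset`."""
    manifest = Path(manifest)
    if manifest.is_dir():
        manifest = manifest / "manifest.tsv"
    table = pd.read_csv(manifest, sep="\t")
    base = manifest.parent
    samples = {}
    for rec in table.itertuples():
        ts = np.loadtxt(base / rec.path, delimiter="\t", ndmin=2)
        samples[(int(rec.subject), int(rec.state))] = ts
    tr = float(table["tr"].iloc[0])
    return StudyDataset(samples, tr, provenance=str(manifest))


def write_ground_truth(truth: GroundTruth, out_dir: str | Path) -> Path:
    """Write precision matrices and an edge-list table (0-based indices)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for (state, band), p in sorted(truth.precisions.items()):
        np.savetxt(out_dir / f"precision_state{state:02d}_band{band}.tsv", p, delimiter="\t")
        for i, j in sorted(truth.supports[(state, band)]):
            rows.append({"node_i": i, "node_j": j, "state": state, "band": band,
                         "precision_value": p[i, j]})
    for state, amp in sorted(truth.amplitudes.items()):
        np.savetxt(out_dir / f"amplitude_state{state:02d}.tsv", amp, delimiter="\t")
    edges = out_dir / "edges.tsv"
    pd.DataFrame(rows).to_csv(edges, sep="\t", index=False)
    return edges
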