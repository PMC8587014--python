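"""Synthetic two-cohort generator of coupled band-limited cortical sources.

Each subject is a set of ROI time series built as a sum over frequency
bands of band-limited Gaussian noise sources.  Within a band that carries
a :class:`TopologySpec`, sources are linearly mixed along the edges of a
Watts-Strogatz-style coupling graph with a fixed sample delay, so the
planted dependence is *lagged* — the only kind of dependence that lagged
linear connectivity detects.  Broadband white noise is added on top.

A subtlety dictates the mixing scheme: if two sources with equal spectra
influence each other symmetrically with the same delay, the two delayed
cross terms ``c P e^{-iωL}`` and ``c P e^{+iωL}`` sum to a purely *real*
cross-spectrum and the planted edge becomes invisible to a lagged
measure.  Each undirected edge is therefore randomly oriented and the
delayed influence flows one way only.

Seeding is splittable: subject ``i`` of a cohort draws from
``SeedSequence(cohort.seed, spawn_key=(i, ...))`` so adding subjects never
perturbs earlier ones, and two cohorts with different seeds are
independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .bands import BAND_NAMES, get_band
from .errors import InvalidSpecError
from .recording import EpochedRecording, default_roi_labels

__all__ = [
    "TopologySpec",
    "CohortSpec",
    "make_coupling_graph",
    "orient_edges",
    "simulate_subject",
    "simulate_cohorts",
    "write_cohort",
    "read_cohort",
]


@dataclass(frozen=True)
class TopologySpec:
    """Coupling topology of one frequency band.

    Parameters
    ----------
    n_nodes : int
        Number of ROIs/nodes (default 84).
    model : {"lattice", "random", "smallworld"}
        ``lattice`` is the ring lattice (rewiring probability 0),
        ``random`` a full Watts-Strogatz rewiring (probability 1), and
        ``smallworld`` uses ``rewiring_prob``.
    rewiring_prob : float
        Watts-Strogatz rewiring probability, used by ``smallworld``.
    degree : int
        Even number of ring-lattice neighbours per node.
    coupling_strength : float
        Gain applied to each delayed neighbour signal.
    coupling_lag : int
        Delay in samples (>= 1; a zero lag would plant purely
        instantaneous dependence, invisible to lagged connectivity).
    """

    n_nodes: int = 84
    model: str = "smallworld"
    rewiring_prob: float = 0.1
    degree: int = 4
    coupling_strength: float = 0.6
    coupling_lag: int = 4

    def __post_init__(self) -> None:
        if self.model not in ("lattice", "random", "smallworld"):
            raise InvalidSpecError(f"unknown topology model {self.model!r}")
        if not 0.0 <= self.rewiring_prob <= 1.0:
            raise InvalidSpecError("rewiring_prob must lie in [0, 1]")
        if self.degree >= self.n_nodes:
            raise InvalidSpecError(
                f"degree ({self.degree}) must be < n_nodes ({self.n_nodes})"
            )
        if self.degree < 2 or self.degree % 2:
            raise InvalidSpecError("degree must be an even count >= 2")
        if self.coupling_lag < 1:
            raise InvalidSpecError("coupling_lag must be >= 1 sample")
        if self.coupling_strength < 0:
            raise InvalidSpecError("coupling_strength must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """One cohort of subjects sharing a generative model.

    ``band_topologies`` maps canonical band names to the
    :class:`TopologySpec` planted in that band; bands without an entry
    carry no coupled source (broadband noise only).
    """

    n_subjects: int = 13
    duration_s: float = 360.0
    fs: float = 256.0
    band_topologies: Mapping[str, TopologySpec] = field(default_factory=dict)
    noise_sd: float = 1.0
    seed: int = 0
    n_nodes: int = 84
    epoch_length_s: float = 2.0

    def __post_init__(self) -> None:
        for name, topo in self.band_topologies.items():
            band = get_band(name)  # raises for non-canonical names
            if self.fs <= 2 * band.hi:
                raise InvalidSpecError(
                    f"fs={self.fs} violates Nyquist for band {name} "
                    f"(needs fs > {2 * band.hi})"
                )
            if topo.n_nodes != self.n_nodes:
                raise InvalidSpecError(
                    f"band {name}: topology n_nodes={topo.n_nodes} != "
                    f"cohort n_nodes={self.n_nodes}"
                )
        if self.n_subjects < 1:
            raise InvalidSpecError("n_subjects must be >= 1")
        if self.duration_s < self.epoch_length_s:
            raise InvalidSpecError("duration_s shorter than one epoch")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")


def make_coupling_graph(spec: TopologySpec, rng_seed: int) -> np.ndarray:
    """Build the binary symmetric coupling adjacency for one band.

    ``lattice`` returns the exact ring lattice, ``random`` a full
    rewiring (probability 1), ``smallworld`` the Watts-Strogatz rewiring
    at ``spec.rewiring_prob``.  Rewiring preserves the edge count
    ``n_nodes * degree / 2``.
    """
    p = {"lattice": 0.0, "random": 1.0}.get(spec.model, spec.rewiring_prob)
    g = nx.watts_strogatz_graph(
        spec.n_nodes, spec.degree, p, seed=int(rng_seed) & 0x7FFFFFFF
    )
    adj = nx.to_numpy_array(g, nodelist=range(spec.n_nodes), dtype=float)
    return adj


def orient_edges(adjacency: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Assign each undirected edge a random direction.

    Returns a matrix ``D`` with ``D[i, j] = 1`` meaning source ``j``
    drives node ``i`` (after the coupling delay).
    """
    iu, ju = np.nonzero(np.triu(adjacency, k=1))
    flip = rng.random(iu.size) < 0.5
    D = np.zeros_like(adjacency)
    # edge (i, j): either j -> i or i -> j
    D[np.where(flip, iu, ju), np.where(flip, ju, iu)] = 1.0
    return D


def _band_limited_noise(
    rng: np.random.Generator, n_nodes: int, n_samples: int, fs: float, lo: float, hi: float
) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [lo, hi) by spectral masking."""
    white = rng.standard_normal((n_nodes, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    spec[:, ~((freqs >= lo) & (freqs < hi))] = 0.0
    sig = np.fft.irfft(spec, n=n_samples, axis=-1)
    sd = sig.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return sig / sd


def _subject_seedseq(cohort_seed: int, subject_index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(cohort_seed, spawn_key=(subject_index,))


def simulate_subject(
    cohort: CohortSpec,
    subject_index: int,
    rng_seed: int | None = None,
    subject_id: str | None = None,
    group: str = "unknown",
) -> EpochedRecording:
    """Simulate one subject of a cohort.

    Deterministic given ``(rng_seed, subject_index)``; ``rng_seed``
    defaults to ``cohort.seed``.
    """
    seed = cohort.seed if rng_seed is None else rng_seed
    n_samples = int(round(cohort.duration_s * cohort.fs))
    x = np.zeros((cohort.n_nodes, n_samples))

    for k, name in enumerate(BAND_NAMES):
        topo = cohort.band_topologies.get(name)
        if topo is None:
            continue
        band = get_band(name)
        ss = np.random.SeedSequence(seed, spawn_key=(subject_index, k))
        rng = np.random.default_rng(ss)
        graph_seed = int(ss.generate_state(1, dtype=np.uint32)[0])
        adj = make_coupling_graph(topo, graph_seed)
        D = orient_edges(adj, rng)
        s = _band_limited_noise(
            rng, cohort.n_nodes, n_samples, cohort.fs, band.lo, band.hi
        )
        delayed = np.roll(s, topo.coupling_lag, axis=-1)
        x += s + topo.coupling_strength * (D @ delayed)

    noise_rng = np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(subject_index, len(BAND_NAMES)))
    )
    x += cohort.noise_sd * noise_rng.standard_normal(x.shape)

    spe = int(round(cohort.fs * cohort.epoch_length_s))
    n_ep = n_samples // spe
    data = x[:, : n_ep * spe].reshape(cohort.n_nodes, n_ep, spe).transpose(1, 0, 2)
    return EpochedRecording(
        subject_id=subject_id or f"S{subject_index:02d}",
        group=group,
        fs=cohort.fs,
        roi_labels=default_roi_labels(cohort.n_nodes),
        data=data,
        epoch_length_s=cohort.epoch_length_s,
        meta={"seed": int(seed), "subject_index": int(subject_index)},
    )


def simulate_cohorts(
    pd_like: CohortSpec, nold_like: CohortSpec
) -> list[EpochedRecording]:
    """Simulate the two labelled cohorts (groups ``PD`` and ``Nold``)."""
    if pd_like.fs != nold_like.fs:
        raise InvalidSpecError(
            f"cohorts must share fs (got {pd_like.fs} and {nold_like.fs})"
        )
    if pd_like.duration_s != nold_like.duration_s:
        raise InvalidSpecError("cohorts must share duration_s")
    recs: list[EpochedRecording] = []
    for group, spec in (("PD", pd_like), ("Nold", nold_like)):
        for i in range(spec.n_subjects):
            recs.append(
                simulate_subject(
                    spec, i, subject_id=f"{group}-{i + 1:02d}", group=group
                )
            )
    return recs


def write_cohort(recordings: Sequence[EpochedRecording], out_dir: str | Path) -> Path:
    """Write per-subject CSV + JSON sidecars and a cohort manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        fname = f"{rec.subject_id}.csv"
        rec.write_csv(out_dir / fname)
        rows.append({"subject_id": rec.subject_id, "group": rec.group, "file": fname})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path: str | Path) -> list[EpochedRecording]:
    """Read a cohort written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    recs = []
    for _, row in table.iterrows():
        rec = EpochedRecording.read_csv(manifest_path.parent / row["file"])
        recs.append(replace(rec, group=str(row["group"])))
    return recs
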