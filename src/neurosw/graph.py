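"""Weighted graph metrics and the cross-band-normalized small-world index.

Nodes are ROIs; edge weights are the band's lagged connectivity values.
Two metrics are computed per subject per band:

* weighted clustering coefficient ``C_w`` — the Onnela geometric-mean
  form, ``C_i = (1/(k_i (k_i-1))) sum_{j,h} (w'_ij w'_ih w'_jh)^(1/3)``
  with weights rescaled by the matrix maximum (``w' = W / max W``) and
  ``k_i`` the number of nonzero-weight neighbours; ``C_w`` is the node
  average.  Reduces to the binary clustering coefficient on 0/1 weights.
* weighted characteristic path length ``L_w`` — mean over ordered node
  pairs of the shortest-path distance with edge lengths ``1 / w``.

Within each subject, both metrics are normalized by their mean over the
seven bands, making the per-band profile a within-subject contrast (the
band factor of the repeated-measures design); the small-world index is
``SW = C_norm / L_norm``, which therefore clusters around 1.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .bands import BAND_NAMES
from .connectivity import ConnectivityMatrix
from .errors import (
    DisconnectedGraphError,
    IncompleteDesignError,
    InvalidSpecError,
    UndefinedMetricError,
)

__all__ = [
    "weighted_clustering",
    "weighted_path_length",
    "metrics_table",
    "normalize_across_bands",
    "small_world",
    "compute_sw_table",
    "group_band_summary",
]

_NORM_TOL = 1e-12


def _check_weights(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise InvalidSpecError(f"weight matrix must be square, got {W.shape}")
    if np.abs(W - W.T).max(initial=0.0) > 1e-12:
        raise InvalidSpecError("weight matrix must be symmetric")
    if (W < 0).any():
        raise InvalidSpecError("weights must be nonnegative")
    if np.diag(W).any():
        raise InvalidSpecError("weight matrix must have a zero diagonal")
    return W


def weighted_clustering(W: np.ndarray) -> float:
    """Onnela geometric-mean weighted clustering coefficient (node average)."""
    W = _check_weights(W)
    mx = W.max()
    if mx == 0:
        raise UndefinedMetricError("clustering undefined for an all-zero graph")
    Wh = np.cbrt(W / mx)
    k = (W > 0).sum(axis=1)
    tri = np.diag(Wh @ Wh @ Wh)  # sum over ordered (j, h) of w'^(1/3) products
    C = np.zeros(W.shape[0])
    ok = k >= 2
    C[ok] = tri[ok] / (k[ok] * (k[ok] - 1.0))
    return float(C.mean())


def _floyd_warshall(D: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths by vectorized Floyd-Warshall relaxation."""
    dist = D.copy()
    for k in range(dist.shape[0]):
        np.minimum(dist, dist[:, k, None] + dist[None, k, :], out=dist)
    return dist


def weighted_path_length(W: np.ndarray) -> float:
    """Mean shortest-path distance over ordered pairs, edge length 1/w.

    Zero weights are treated as absent edges; if that disconnects any
    pair, :class:`DisconnectedGraphError` is raised listing offenders.
    """
    W = _check_weights(W)
    n = W.shape[0]
    if n < 2:
        raise UndefinedMetricError("path length needs at least 2 nodes")
    with np.errstate(divide="ignore"):
        D = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), np.inf)
    np.fill_diagonal(D, 0.0)
    dist = _floyd_warshall(D)
    off = ~np.eye(n, dtype=bool)
    if np.isinf(dist[off]).any():
        bad = np.argwhere(np.isinf(dist) & off)
        pairs = [tuple(map(int, p)) for p in bad[:10]]
        raise DisconnectedGraphError(
            f"graph disconnected; unreachable pairs include {pairs}"
        )
    return float(dist[off].mean())


def metrics_table(
    matrices: Mapping[tuple[str, str], Mapping[str, ConnectivityMatrix]]
) -> pd.DataFrame:
    """Raw per-subject per-band metrics.

    ``matrices`` maps ``(subject_id, group)`` to a band-name ->
    :class:`ConnectivityMatrix` mapping.  Returns a tidy frame with
    columns subject, group, band, C_w, L_w.
    """
    rows = []
    for (subject, group), per_band in matrices.items():
        for band_name, cm in per_band.items():
            rows.append(
                {
                    "subject": subject,
                    "group": group,
                    "band": band_name,
                    "C_w": weighted_clustering(cm.W),
                    "L_w": weighted_path_length(cm.W),
                }
            )
    return pd.DataFrame(rows)


def normalize_across_bands(df: pd.DataFrame) -> pd.DataFrame:
    """Divide each subject's C_w and L_w by their mean over the 7 bands.

    Requires the complete canonical band set per subject; the
    normalized values average to exactly 1 within each subject (checked
    to 1e-12 on every call).
    """
    df = df.copy()
    for subject, sub in df.groupby("subject"):
        missing = set(BAND_NAMES) - set(sub["band"])
        if missing or len(sub) != len(BAND_NAMES):
            raise IncompleteDesignError(
                f"subject {subject}: needs exactly the bands {BAND_NAMES}, "
                f"missing {sorted(missing)}"
            )
    for col, norm_col in (("C_w", "C_norm"), ("L_w", "L_norm")):
        df[norm_col] = df[col] / df.groupby("subject")[col].transform("mean")
        check = df.groupby("subject")[norm_col].mean()
        if not np.allclose(check, 1.0, atol=_NORM_TOL, rtol=0):
            raise AssertionError(
                f"normalization conservation violated for {norm_col}: "
                f"max deviation {np.abs(check - 1).max():.3e}"
            )
    return df


def small_world(df: pd.DataFrame) -> pd.DataFrame:
    """Append the small-world index ``SW = C_norm / L_norm``."""
    df = df.copy()
    df["SW"] = df["C_norm"] / df["L_norm"]
    return df


def compute_sw_table(
    matrices: Mapping[tuple[str, str], Mapping[str, ConnectivityMatrix]]
) -> pd.DataFrame:
    """Full SW table from per-subject connectivity stacks."""
    return small_world(normalize_across_bands(metrics_table(matrices)))


def group_band_summary(sw: pd.DataFrame, value: str = "SW") -> pd.DataFrame:
    """Wide group x band summary (mean and standard error of the mean).

    With a single subject per group the SE is undefined and left blank.
    """
    out = {}
    for group, sub in sw.groupby("group"):
        piv = sub.pivot(index="subject", columns="band", values=value)
        cols = [b for b in BAND_NAMES if b in piv.columns]
        cols += [b for b in piv.columns if b not in BAND_NAMES]
        piv = piv[cols]
        mean = piv.mean(axis=0)
        if len(piv) > 1:
            se = piv.std(axis=0, ddof=1) / np.sqrt(len(piv))
        else:
            import warnings

            warnings.warn(
                f"group {group} has a single subject; SE undefined", stacklevel=2
            )
            se = pd.Series(np.nan, index=mean.index)
        out[(group, "mean")] = mean
        out[(group, "SE")] = se
    summary = pd.DataFrame(out).T
    summary.index.names = ["group", "stat"]
    return summary
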