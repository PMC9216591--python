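"""Perturbation-response scanning: response matrix, profiles, and clustering.

Perturbing node i with a unit force and reading the displacement of node j
through the GNM covariance yields the response matrix P.  Under the default
``squared`` convention P_ij = C_ij^2 / C_ii^2: the elementwise-squared
covariance with each row normalized by its squared diagonal, so every
response is a nonnegative magnitude and the self-response P_ii is 1.  The
``linear`` convention P_ij = C_ij / C_ii keeps the signed linear response.
Normalizing by the node-specific variance sigma_i removes the intrinsic
topology-defined adaptability bias of each perturbed node and breaks the
symmetry of the covariance.

Row averages of P give the *effectiveness* profile (how strongly a node's
perturbation spreads through the network); column averages give the
*sensitivity* profile (how strongly a node responds to perturbations applied
anywhere).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .gnm import Covariance

logger = logging.getLogger(__name__)


@dataclass
class PRSResult:
    """PRS matrix with effectiveness (row-mean) and sensitivity (col-mean)."""

    nodes: list
    matrix: np.ndarray
    convention: str
    include_diagonal: bool = True

    @property
    def effectiveness(self) -> pd.Series:
        return pd.Series(self._axis_mean(axis=1), index=self.nodes)

    @property
    def sensitivity(self) -> pd.Series:
        return pd.Series(self._axis_mean(axis=0), index=self.nodes)

    def _axis_mean(self, axis: int) -> np.ndarray:
        p = self.matrix
        if self.include_diagonal:
            return p.mean(axis=axis)
        n = p.shape[0]
        return (p.sum(axis=axis) - np.diag(p)) / (n - 1)


@dataclass
class DistinctClusters:
    """Smaller top-level sub-tree of the PRS-matrix dendrogram."""

    axis: str  # "perturbed-rows" or "responding-columns"
    linkage: np.ndarray
    distinct_members: list
    degenerate: bool = False


def compute_prs(
    cov: Covariance,
    convention: str = "squared",
    include_diagonal: bool = True,
) -> PRSResult:
    """Compute the PRS matrix from a GNM covariance.

    Parameters
    ----------
    cov
        Covariance from :func:`prscan.gnm.compute_covariance`.
    convention
        ``"squared"`` (default): P_ij = C_ij^2 / C_ii^2, nonnegative response
        magnitudes.  ``"linear"``: P_ij = C_ij / C_ii, signed.
    include_diagonal
        Whether the self-response (always 1) enters the row/column means.  It
        shifts every profile by the same constant and cannot change rankings.

    Notes
    -----
    P is invariant to the spring constant gamma: scaling C by any positive
    factor cancels in the row normalization.
    """
    c = cov.matrix
    sigma = np.diag(c)
    if np.any(sigma <= 0):
        raise ValueError("non-positive square fluctuation sigma_i")
    if convention == "squared":
        p = (c**2) / (sigma**2)[:, None]
    elif convention == "linear":
        p = c / sigma[:, None]
    else:
        raise ValueError(f"unknown convention {convention!r}")
    np.fill_diagonal(p, 1.0)
    return PRSResult(
        nodes=list(cov.nodes),
        matrix=p,
        convention=convention,
        include_diagonal=include_diagonal,
    )


def profiles_frame(prs: PRSResult, net=None) -> pd.DataFrame:
    """Node table of effectiveness/sensitivity (and degree when net given)."""
    df = pd.DataFrame(
        {
            "effectiveness": prs.effectiveness,
            "sensitivity": prs.sensitivity,
        }
    )
    df.index.name = "node"
    if net is not None:
        df.insert(0, "degree", pd.Series(dict(net.degree()), dtype=int))
    return df


def cluster_prs_matrix(
    prs: PRSResult, axis: str = "perturbed-rows", cap_quantile: float = 0.95
) -> DistinctClusters:
    """Hierarchically cluster PRS rows or columns; return the distinct cluster.

    Outliers above the ``cap_quantile`` of all matrix entries are winsorized
    to that quantile.  Observations (rows for the perturbed axis, columns for
    the responding axis) are compared by standardized Euclidean distance and
    merged with Ward linkage; cutting the tree at the top-level merge gives
    two clusters, of which the smaller is the distinct perturbed (or
    responding) gene cluster.
    """
    if axis not in ("perturbed-rows", "responding-columns"):
        raise ValueError(f"unknown axis {axis!r}")
    p = prs.matrix
    n = p.shape[0]
    if n < 4:
        raise ValueError("clustering requires at least 4 nodes")
    cap = np.quantile(p, cap_quantile)
    capped = np.minimum(p, cap)
    obs = capped if axis == "perturbed-rows" else capped.T

    var = obs.var(axis=0, ddof=1)
    keep = var > 0
    if not keep.all():
        logger.info("dropping %d zero-variance coordinates", int((~keep).sum()))
    obs = obs[:, keep]
    if obs.shape[1] == 0:
        raise ValueError("all coordinates are degenerate (identical observations)")

    dist = pdist(obs, metric="seuclidean")
    link = hierarchy.ward(dist)
    labels = hierarchy.fcluster(link, t=2, criterion="maxclust")
    sizes = {lab: int(np.sum(labels == lab)) for lab in np.unique(labels)}
    if len(sizes) < 2:
        raise ValueError("degenerate input: dendrogram cannot be split in two")
    small = min(sizes, key=lambda lab: (sizes[lab], lab))
    members = [prs.nodes[i] for i in np.nonzero(labels == small)[0]]
    degenerate = len(members) == 1
    if degenerate:
        logger.warning("top-level split yields a singleton distinct cluster")
    return DistinctClusters(
        axis=axis, linkage=link, distinct_members=members, degenerate=degenerate
    )
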