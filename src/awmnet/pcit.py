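"""PCIT: partial-correlation edge significance with an information-theoretic
tolerance.

For every trio of variables (x, y, z) the three first-order partial
correlations are computed; their average ratio to the corresponding direct
correlations is the trio's tolerance epsilon. The edge (x, y) is flagged
non-significant by trio z when

    |r_xy| <= |eps * r_xz|  and  |r_xy| <= |eps * r_yz|

i.e. z explains the x-y association up to tolerance. An edge survives iff
no trio flags it. The implementation vectorizes over (x, y) for each
conditioning z and is outcome-identical to the cubic scalar reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .awm import AWM

__all__ = [
    "CorrelationMatrix",
    "correlate_rows",
    "first_order_partial",
    "pcit",
    "build_network",
    "EmptyNetworkWarning",
]

_SINGULAR_TOL = 1e-12


class EmptyNetworkWarning(UserWarning):
    """PCIT retained no edge; downstream stages should skip gracefully."""


@dataclass
class CorrelationMatrix:
    node_ids: list[str]
    r: np.ndarray
    excluded_constant: list[str]

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if r.shape[0] != r.shape[1] or r.shape[0] != len(self.node_ids):
            raise ValueError("correlation matrix shape mismatch")
        if not np.allclose(r, r.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        self.r = r


def correlate_rows(awm: AWM) -> CorrelationMatrix:
    """Pearson correlation between every pair of AWM rows across trait
    columns. Constant rows are excluded (flagged) before correlating."""
    M = awm.matrix.to_numpy(dtype=float)
    if M.shape[1] < 3:
        raise ValueError("need >= 3 trait columns for meaningful row correlations")
    sd = M.std(axis=1)
    const = sd == 0
    excluded = [awm.snp_ids[i] for i in np.nonzero(const)[0]]
    if excluded:
        warnings.warn(f"{len(excluded)} constant AWM rows excluded from correlation")
    keep = ~const
    ids = [awm.snp_ids[i] for i in np.nonzero(keep)[0]]
    r = np.corrcoef(M[keep])
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(ids, r, excluded)


def first_order_partial(r_xy: float, r_xz: float, r_yz: float) -> float:
    """r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2));
    NaN when a conditioning correlation is (numerically) +/-1."""
    for v in (r_xy, r_xz, r_yz):
        if abs(v) > 1.0 + 1e-9:
            raise ValueError("correlations must lie in [-1, 1]")
    den = (1.0 - r_xz * r_xz) * (1.0 - r_yz * r_yz)
    if den < _SINGULAR_TOL:
        return float("nan")
    return (r_xy - r_xz * r_yz) / np.sqrt(den)


def pcit(corr: CorrelationMatrix | np.ndarray) -> np.ndarray:
    """Boolean significance mask over edges (i, j), i != j, symmetric.

    Trios containing a numerically singular partial (conditioning
    correlation at +/-1) or a zero direct correlation (tolerance ratio
    undefined) are skipped; with fewer than 3 nodes every edge is retained
    by convention (no possible conditioning variable).
    """
    r = corr.r if isinstance(corr, CorrelationMatrix) else np.asarray(corr, dtype=float)
    n = r.shape[0]
    sig = np.ones((n, n), dtype=bool)
    np.fill_diagonal(sig, False)
    if n < 3:
        return sig

    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        one_minus_sq = 1.0 - r * r  # 1 - r_xy^2 as [x, y]
        for z in range(n):
            rz_col = r[:, z][:, None]  # r_xz over rows
            rz_row = r[z, :][None, :]  # r_yz over cols
            d_xz = 1.0 - rz_col * rz_col
            d_yz = 1.0 - rz_row * rz_row
            # P[x,y] = r_xy.z ; B[x,y] = r_xz.y ; C[x,y] = r_yz.x
            P = (r - rz_col * rz_row) / np.sqrt(d_xz * d_yz)
            B = (rz_col - r * rz_row) / np.sqrt(one_minus_sq * d_yz)
            C = (rz_row - r * rz_col) / np.sqrt(one_minus_sq * d_xz)
            eps = (P / r + B / rz_col + C / rz_row) / 3.0
            cond = (np.abs(r) <= np.abs(eps * rz_col)) & (np.abs(r) <= np.abs(eps * rz_row))
            valid = (
                off
                & np.isfinite(eps)
                & (np.arange(n)[:, None] != z)
                & (np.arange(n)[None, :] != z)
                & (d_xz >= _SINGULAR_TOL)
                & (d_yz >= _SINGULAR_TOL)
                & (one_minus_sq >= _SINGULAR_TOL)
            )
            sig &= ~(cond & valid)
    sig &= sig.T  # symmetry guard (flagging is already symmetric in x, y)
    return sig


def build_network(
    awm: AWM,
    corr: CorrelationMatrix,
    mask: np.ndarray,
    min_abs_weight: float = 0.0,
) -> nx.Graph:
    """Co-association graph: significant edges weighted by the direct
    correlation; isolated nodes dropped; node attributes carry the mapped
    gene for downstream annotation. ``min_abs_weight`` optionally imposes
    a raw-correlation floor on retained edges."""
    g = nx.Graph()
    meta = awm.row_meta.set_index("snp_id") if len(awm.row_meta) else None
    ids = corr.node_ids
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if mask[i, j] and abs(corr.r[i, j]) >= min_abs_weight:
                g.add_edge(ids[i], ids[j], weight=float(corr.r[i, j]))
    for node in g.nodes:
        if meta is not None and node in meta.index and "gene_id" in meta.columns:
            g.nodes[node]["gene_id"] = str(meta.at[node, "gene_id"])
    if g.number_of_edges() == 0:
        warnings.warn("PCIT retained no significant edge", EmptyNetworkWarning)
    return g


def network_summary(g: nx.Graph) -> pd.Series:
    return pd.Series(
        {"nodes": g.number_of_nodes(), "edges": g.number_of_edges()}, dtype=int
    )
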