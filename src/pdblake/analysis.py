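"""Consecutive Cα–Cα distances per chain and fuzzy "around 3.81 Å" selection.

In a trans polypeptide the alpha-carbons of adjacent residues sit close to
3.81 Å apart, so the distance between successive Cα atoms is a cheap sanity
feature of a protein backbone.  Rather than a hard window, selection here is
a fuzzy query: the distance d is graded by a Gaussian membership function

    mu(d) = exp(-(d - c)^2 / (2 sigma^2)),      c = 3.81 A by default,

and a pair is kept when mu(d) reaches the minimum degree of truth lambda
(default 0.5).  mu is 1 exactly at the center and decays symmetrically, so
the lambda-cut is the closed interval  |d - c| <= sigma * sqrt(2 ln(1/lambda)).

The default width sigma = 0.04 A places mu(3.78) above and mu(3.87) below
the default cut, i.e. a 0.03 A deviation still passes while a 0.06 A
deviation does not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FuzzySet",
    "euclidean_distance",
    "gaussian_membership",
    "consecutive_ca_distances",
    "fuzzy_filter",
    "DISTANCE_COLUMNS",
]

#: schema of the distance report (residue context + distance + membership)
DISTANCE_COLUMNS = [
    "proteinId", "modelId", "chainId",
    "resSeqFrom", "resNameFrom", "resSeqTo", "resNameTo",
    "seqGap", "distance", "membership",
]

DEFAULT_CENTER = 3.81
DEFAULT_SIGMA = 0.04
DEFAULT_LAMBDA = 0.5


@dataclass(frozen=True)
class FuzzySet:
    """Gaussian fuzzy set "around *center* Å" with a lambda-cut threshold."""

    center: float = DEFAULT_CENTER
    sigma: float = DEFAULT_SIGMA
    lambda_cut: float = DEFAULT_LAMBDA

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.lambda_cut <= 1.0:
            raise ValueError("lambda_cut must lie in [0, 1]")

    def membership(self, x):
        return gaussian_membership(x, self)

    @property
    def cut_halfwidth(self) -> float:
        """Half-width of the lambda-cut interval, sigma*sqrt(2 ln(1/lambda))."""
        if self.lambda_cut == 0.0:
            return math.inf
        return self.sigma * math.sqrt(2.0 * math.log(1.0 / self.lambda_cut))


def euclidean_distance(p, q) -> float:
    """Distance between two points, written out as the explicit Euclidean sum.

    Equivalent to the vector-norm form ||p - q||; the explicit form is kept
    so the two can be cross-checked independently.
    """
    (x1, y1, z1), (x2, y2, z2) = p, q
    if not all(map(math.isfinite, (x1, y1, z1, x2, y2, z2))):
        raise ValueError("coordinates must be finite")
    return math.sqrt((x2 - x1) ** 2 + (y2 - y1) ** 2 + (z2 - z1) ** 2)


def gaussian_membership(x, fs: FuzzySet | None = None):
    """Membership degree exp(-(x - center)^2 / (2 sigma^2)), vectorized."""
    fs = fs or FuzzySet()
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("distance values must be finite")
    mu = np.exp(-((x - fs.center) ** 2) / (2.0 * fs.sigma**2))
    return float(mu) if mu.ndim == 0 else mu


def consecutive_ca_distances(rows: pd.DataFrame) -> pd.DataFrame:
    """Distances between successive Cα atoms within each chain.

    *rows* is an ATOM rowset.  Within every (proteinId, modelId, chainId)
    group, Cα atoms are taken in file order — one per residue, the first
    alternate location winning — and one distance row is emitted per
    adjacent pair.  Pairs never span chain, model or protein boundaries;
    chains with fewer than two Cα atoms emit nothing.  ``seqGap`` records
    ``resSeqTo - resSeqFrom`` so pairs that bridge missing residues can be
    filtered downstream.

    Adjacency follows file order (the sliding window over extracted rows),
    not residue-number arithmetic, so insertion codes and numbering gaps do
    not silently reorder pairs.
    """
    if rows.empty:
        return _empty_distances()
    ca = rows[(rows["recordName"] == "ATOM") & (rows["atomName"] == "CA")]
    if ca.empty:
        return _empty_distances()
    # first altLoc occurrence per residue, in file order
    ca = ca.drop_duplicates(
        subset=["proteinId", "modelId", "chainId", "resSeq", "iCode"],
        keep="first",
    )

    out: list[pd.DataFrame] = []
    for (protein, model, chain), g in ca.groupby(
        ["proteinId", "modelId", "chainId"], sort=False
    ):
        if len(g) < 2:
            continue
        xyz = g[["x", "y", "z"]].to_numpy(dtype=float)
        d = np.sqrt(np.sum(np.diff(xyz, axis=0) ** 2, axis=1))
        res = g["resSeq"].to_numpy()
        names = g["resName"].to_numpy()
        out.append(pd.DataFrame({
            "proteinId": protein,
            "modelId": model,
            "chainId": chain,
            "resSeqFrom": res[:-1],
            "resNameFrom": names[:-1],
            "resSeqTo": res[1:],
            "resNameTo": names[1:],
            "seqGap": res[1:] - res[:-1],
            "distance": d,
            "membership": np.nan,
        }))
    if not out:
        return _empty_distances()
    return pd.concat(out, ignore_index=True)


def _empty_distances() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in DISTANCE_COLUMNS})


def fuzzy_filter(rows: pd.DataFrame, fs: FuzzySet | None = None) -> pd.DataFrame:
    """Keep distance rows whose membership reaches the lambda-cut.

    Fills the ``membership`` column with mu(distance) and retains rows with
    mu >= lambda_cut, preserving input order.  The comparison is >= so that
    lambda = 1 keeps exactly the center and lambda = 0 keeps everything.
    """
    fs = fs or FuzzySet()
    if rows.empty:
        return rows.copy()
    out = rows.copy()
    mu = gaussian_membership(out["distance"].to_numpy(dtype=float), fs)
    out["membership"] = mu
    return out[out["membership"] >= fs.lambda_cut].reset_index(drop=True)
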