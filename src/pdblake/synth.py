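"""Synthetic PDB corpora: seeded toy polypeptides for testing without downloads.

Entries are chemically naive but column-valid: per residue an N, CA, C
backbone triplet is written, with consecutive Cα atoms exactly ``spacing``
apart (default 3.81 Å, the trans-peptide Cα–Cα distance) before optional
isotropic Gaussian noise.  The Cα trace is an axis-aligned random walk —
each step moves one ``spacing`` along a random ±axis, never immediately
reversing — so that noise-free coordinates are exact multiples of the
spacing and survive the fixed-width ``%8.3f`` quantization unchanged.

Noise model: after placement, every Cα is displaced by an independent
N(0, noise_sd²·I₃) vector.  The displacement difference between two
adjacent Cα atoms is then N(0, 2·noise_sd²·I₃), so the squared distance
divided by 2·noise_sd² follows a noncentral chi-square with 3 degrees of
freedom and noncentrality spacing²/(2·noise_sd²) —
:func:`expected_kept_fraction` turns that into the closed-form probability
that a pair survives a Gaussian lambda-cut, which parameter-recovery tests
compare against the empirical kept fraction.

Identical ``FixtureSpec`` (including seed) produces byte-identical output;
gzip members are written with a fixed mtime for that reason.
"""

from __future__ import annotations

import gzip
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
from scipy.stats import ncx2

from .analysis import FuzzySet
from .store import StoreConfig, concat_entries

__all__ = [
    "FixtureSpec",
    "make_polypeptide",
    "make_corpus",
    "expected_kept_fraction",
]

AMINO_ACIDS = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]

CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

# six axis-aligned unit steps; index ^ 1 is the reverse of index
_STEPS = np.array([
    [1, 0, 0], [-1, 0, 0],
    [0, 1, 0], [0, -1, 0],
    [0, 0, 1], [0, 0, -1],
], dtype=float)

# coordinates must stay within the %8.3f field: (-999.999, 9999.999)
_BOX_LO, _BOX_HI = -900.0, 9900.0

# backbone offsets of N and C from their residue's Cα (fixed, naive)
_N_OFFSET = np.array([-0.8, 1.1, 0.0])
_C_OFFSET = np.array([0.9, 1.1, 0.0])


@dataclass
class FixtureSpec:
    """Parameters of a synthetic corpus; equal specs give identical bytes."""

    n_entries: int = 1
    n_residues: int = 10
    n_chains: int = 1
    n_models: int = 1
    spacing: float = 3.81
    noise_sd: float = 0.0
    seed: int = 0
    layout: str = "individual"
    compress: bool = False
    with_water: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.n_entries <= 9999:
            raise ValueError("n_entries must be in [0, 9999]")
        if not 1 <= self.n_residues <= 9999:
            raise ValueError("n_residues must be in [1, 9999] (4-column resSeq)")
        if not 1 <= self.n_chains <= len(CHAIN_IDS):
            raise ValueError(f"n_chains must be in [1, {len(CHAIN_IDS)}]")
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.layout not in ("individual", "sequential"):
            raise ValueError("layout must be 'individual' or 'sequential'")


def _ca_walk(rng: np.random.Generator, n: int, spacing: float) -> np.ndarray:
    """Axis-aligned random walk of n Cα positions, step length = spacing."""
    pos = np.zeros((n, 3))
    prev_dir = -1
    cur = np.zeros(3)
    for i in range(1, n):
        while True:
            d = int(rng.integers(0, 6))
            if prev_dir >= 0 and d == (prev_dir ^ 1):
                continue  # no immediate backtracking
            nxt = cur + spacing * _STEPS[d]
            if np.all((nxt > _BOX_LO) & (nxt < _BOX_HI)):
                break
        cur = nxt
        prev_dir = d
        pos[i] = cur
    return pos


def _atom_line(record: str, serial: int, name: str, res: str, chain: str,
               seq: int, xyz: np.ndarray, element: str) -> str:
    name4 = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record:<6s}{serial:5d} {name4} {res:>3s} {chain}{seq:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def make_polypeptide(spec: FixtureSpec, entry_index: int = 0) -> str:
    """Emit one well-formed synthetic PDB entry as text.

    The entry carries a HEADER with a four-digit synthetic idCode, SEQRES
    records (13 residue names per line, numRes matching the ATOM records),
    optional MODEL/ENDMDL blocks, N/CA/C ATOM records per residue, TER per
    chain, an optional HETATM water, and END.
    """
    rng = np.random.default_rng([spec.seed, entry_index])
    id_code = f"{entry_index:04d}"
    residues = [
        AMINO_ACIDS[(entry_index + i) % len(AMINO_ACIDS)]
        for i in range(spec.n_residues)
    ]

    lines: list[str] = [
        "HEADER    " + "SYNTHETIC POLYPEPTIDE".ljust(40)
        + "01-JAN-00".ljust(9) + "   " + id_code
    ]
    for c in range(spec.n_chains):
        chain = CHAIN_IDS[c]
        for start in range(0, spec.n_residues, 13):
            ser = start // 13 + 1
            names = " ".join(f"{r:>3s}" for r in residues[start:start + 13])
            lines.append(
                f"SEQRES {ser:3d} {chain} {spec.n_residues:4d}  {names}"
            )

    for m in range(spec.n_models):
        if spec.n_models > 1:
            lines.append(f"MODEL {m + 1:8d}")
        serial = 0
        for c in range(spec.n_chains):
            chain = CHAIN_IDS[c]
            ca = _ca_walk(rng, spec.n_residues, spec.spacing)
            if spec.noise_sd > 0:
                ca = ca + rng.normal(0.0, spec.noise_sd, ca.shape)
            last_res = residues[-1]
            for i, res in enumerate(residues):
                seq = i + 1
                for name, offset, element in (
                    ("N", _N_OFFSET, "N"),
                    ("CA", np.zeros(3), "C"),
                    ("C", _C_OFFSET, "C"),
                ):
                    serial += 1
                    lines.append(_atom_line(
                        "ATOM", serial, name, res, chain, seq,
                        ca[i] + offset, element,
                    ))
            serial += 1
            lines.append(
                f"TER   {serial:5d}      {last_res:>3s} "
                f"{chain}{spec.n_residues:4d}"
            )
        if spec.with_water:
            serial += 1
            lines.append(_atom_line(
                "HETATM", serial, "O", "HOH",
                CHAIN_IDS[spec.n_chains % len(CHAIN_IDS)],
                1, np.array([-50.0, -50.0, -50.0]), "O",
            ))
        if spec.n_models > 1:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_corpus(spec: FixtureSpec, out_dir: Union[str, Path]) -> list[Path]:
    """Materialize a corpus in the requested layout and compression.

    ``individual`` writes one ``.ent``/``.ent.gz`` file per entry;
    ``sequential`` routes the entries through the sequential store, yielding
    one or more END-delimited concatenations.  Returns the produced paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    texts = [make_polypeptide(spec, i) for i in range(spec.n_entries)]

    if spec.layout == "sequential":
        with tempfile.TemporaryDirectory() as tmp:
            members = []
            for i, text in enumerate(texts):
                p = Path(tmp) / f"pdb{i:04d}.ent"
                p.write_text(text, encoding="latin-1")
                members.append(p)
            if not members:
                return []
            return concat_entries(
                members, StoreConfig(compress=spec.compress), out_dir
            )

    paths: list[Path] = []
    for i, text in enumerate(texts):
        blob = text.encode("latin-1")
        if spec.compress:
            path = out_dir / f"pdb{i:04d}.ent.gz"
            with open(path, "wb") as raw:
                with gzip.GzipFile(filename="", mode="wb", fileobj=raw,
                                   mtime=0) as gz:
                    gz.write(blob)
        else:
            path = out_dir / f"pdb{i:04d}.ent"
            path.write_bytes(blob)
        paths.append(path)
    return paths


def expected_kept_fraction(
    noise_sd: float,
    spacing: float = 3.81,
    fs: FuzzySet | None = None,
) -> float:
    """Closed-form probability that a noisy Cα pair passes the lambda-cut.

    Under the generator's noise model the pair distance d satisfies
    d² / (2·noise_sd²) ~ χ²₃(noncentral, nc = spacing²/(2·noise_sd²)), and
    the lambda-cut keeps d in [center − h, center + h] with
    h = sigma·sqrt(2 ln(1/lambda)).
    """
    fs = fs or FuzzySet()
    h = fs.cut_halfwidth
    if noise_sd == 0:
        return float(abs(spacing - fs.center) <= h)
    if not np.isfinite(h):
        return 1.0
    s2 = 2.0 * noise_sd**2
    nc = spacing**2 / s2
    lo = max(0.0, fs.center - h)
    hi = fs.center + h
    return float(
        ncx2.cdf(hi**2 / s2, 3, nc) - ncx2.cdf(lo**2 / s2, 3, nc)
    )
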