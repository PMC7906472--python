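"""Structural similarity and assignment metrics.

Q value: exponentially weighted fraction of native-like CA-CA distances,

    Q = 2 / ((N-2)(N-3)) * sum_{j >= i+3} exp(-(r_ij - r_ij^N)^2 / (2 sigma_ij^2))
    sigma_ij = (1 + |i - j|)^0.15 A

1 means identical internal geometry. Region-filtered variants restrict the
sum to residues outside (Q_water) or inside (Q_membrane) the membrane slab,
with membership decided from the native structure's CA heights; the membrane
variant doubles sigma_ij. Also here: the membrane-inside fraction chi, the
burial-pattern similarity theta_d used to weight decoys, and CB-distance
disulfide detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .cg_model import CGSystem

__all__ = [
    "QSpec",
    "q_value",
    "chi_fraction",
    "burial_similarity",
    "detect_disulfides",
    "fraction_correct_disulfides",
]


@dataclass(frozen=True)
class QSpec:
    """Configuration of the Q metric.

    mode: 'global', 'water' (residues outside the slab) or 'membrane'
    (residues inside). sigma_prefactor defaults to 1 for global/water and 2
    for membrane mode when left as None.
    """

    mode: str = "global"
    sigma_exponent: float = 0.15
    sigma_prefactor: float | None = None
    zm: float = 15.0

    def __post_init__(self):
        if self.mode not in ("global", "water", "membrane"):
            raise ValueError(f"unknown Q mode {self.mode!r}")
        if self.sigma_prefactor is not None and self.sigma_prefactor <= 0:
            raise ValueError("sigma prefactor must be positive")

    @property
    def prefactor(self) -> float:
        if self.sigma_prefactor is not None:
            return self.sigma_prefactor
        return 2.0 if self.mode == "membrane" else 1.0


def _check_same_residues(native: CGSystem, model: CGSystem) -> None:
    if native.res_keys != model.res_keys or native.res_types != model.res_types:
        raise ValueError("native and model must have identical residue sets")


def q_value(native: CGSystem, model: CGSystem, spec: QSpec = QSpec()) -> float:
    """Similarity of the model's internal CA geometry to the native's."""
    _check_same_residues(native, model)
    z = native.ca_positions()[:, 2]
    if spec.mode == "global":
        sel = np.arange(native.L)
    elif spec.mode == "water":
        sel = np.where(np.abs(z) >= spec.zm)[0]
    else:
        sel = np.where(np.abs(z) < spec.zm)[0]
    n = len(sel)
    if n < 4:
        raise ValueError(
            f"Q undefined: only {n} residues selected in mode {spec.mode!r} (need >= 4)")

    rn = squareform(pdist(native.ca_positions()[sel]))
    rm = squareform(pdist(model.ca_positions()[sel]))
    # |i - j| is the separation in the original sequence, also after filtering
    seq = native.res_seqpos[sel]
    sep = np.abs(seq[:, None] - seq[None, :])
    mask = np.triu(sep >= 3)
    sigma = spec.prefactor * (1.0 + sep) ** spec.sigma_exponent
    gauss = np.exp(-((rm - rn) ** 2) / (2.0 * sigma ** 2))
    return float(2.0 / ((n - 2) * (n - 3)) * np.sum(gauss[mask]))


def chi_fraction(cg: CGSystem, zm: float = 15.0) -> float:
    """Fraction of protein residues with CA strictly inside |z| < zm."""
    z = cg.ca_positions()[:, 2]
    return float(np.mean(np.abs(z) < zm))


def burial_similarity(native: CGSystem, decoy: CGSystem, zm: float = 15.0) -> float:
    """theta_d: fraction of residues with the same inside/outside assignment."""
    if native.L != decoy.L:
        raise ValueError("native and decoy must have the same residue count")
    zn = native.ca_positions()[:, 2]
    zd = decoy.ca_positions()[:, 2]
    return float(np.mean((np.abs(zn) < zm) == (np.abs(zd) < zm)))


def detect_disulfides(cg: CGSystem, bond_cutoff: float = 4.2) -> set[tuple[int, int]]:
    """Greedy closest-first disulfide assignment from CB-CB distances.

    Candidate pairs are cysteines with CB-CB distance <= cutoff and sequence
    separation > 1 (interchain pairs always allowed); each cysteine joins at
    most one bond. Returns residue-table index pairs (i < j).
    """
    cys = cg.cysteine_residues()
    cb = cg.cb_positions()
    candidates = []
    for a in range(len(cys)):
        for b in range(a + 1, len(cys)):
            i, j = int(cys[a]), int(cys[b])
            sep = cg.sequence_separation(i, j)
            if sep is not None and sep <= 1:
                continue
            r = float(np.linalg.norm(cb[i] - cb[j]))
            if r <= bond_cutoff:
                candidates.append((r, i, j))
    bonds: set[tuple[int, int]] = set()
    used: set[int] = set()
    for r, i, j in sorted(candidates):
        if i in used or j in used:
            continue
        bonds.add((i, j))
        used.update((i, j))
    return bonds


def fraction_correct_disulfides(native_pairs: set[tuple[int, int]],
                                model: CGSystem,
                                cutoff: float = 4.2) -> float:
    """Fraction of reference disulfide pairs recovered in the model."""
    if not native_pairs:
        raise ValueError("fraction of correct disulfides undefined: empty native set")
    native_pairs = {tuple(sorted(p)) for p in native_pairs}
    found = detect_disulfides(model, cutoff)
    return len(found & native_pairs) / len(native_pairs)
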