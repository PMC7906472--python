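"""Decoy generation and Z-score coefficient optimization.

Decoys are rigid-body misplacements of a membrane protein: rotations about
the x axis through the CA centroid combined with vertical (z) shifts. The
standard grid is 12 rotations (0-165 degrees in steps of 15) by 20 shifts
(-40 to +36 A in steps of 4), i.e. 240 decoys per protein. Each structure is
summarized by three features,

    phi_wat       = sum_{pairs} (1 - a_i a_j) V_water(i,j)
    phi_mem       = sum_{pairs} a_i a_j V_membrane(i,j)
    phi_memburial = sum_i A(type_i) Theta(z_i, zm)

and scored with E = k_wat phi_wat + k_mem phi_mem + k_memburial phi_memburial.
The funneling of this energy toward the native placement is measured by

    Z = (E_native - <E>_mg) / sigma(E_mg)

where the molten-globule (decoy) moments are weighted by 1 - theta_d, the
burial-pattern dissimilarity of each decoy, so that near-native decoys do not
dilute the contrast. The optimizer searches the coefficients (gauge-fixed to
k_wat = 1) that maximize |Z| in the funneled direction E_native < <E>_mg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .cg_model import CGSystem, MembraneSlab
from .membrane_contact import (ContactParams, HydrophobicityScale,
                               contact_components, membrane_burial_energy)
from .metrics import burial_similarity, chi_fraction

__all__ = [
    "PAPER_ANGLES",
    "PAPER_SHIFTS",
    "DecoySet",
    "OptimizationResult",
    "generate_decoys",
    "phi_features",
    "weighted_decoy_average",
    "z_score",
    "optimize_coefficients",
    "select_training",
]

# canonical rigid-body decoy grids: 12 angles x 20 z-shifts = 240 decoys
PAPER_ANGLES = tuple(range(0, 180, 15))
PAPER_SHIFTS = tuple(range(-40, 40, 4))


def _rot_x(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


@dataclass
class DecoySet:
    """Rigid-body perturbed copies of a source structure.

    ``features`` rows are (phi_wat, phi_mem, phi_memburial) per decoy;
    ``theta_d`` is each decoy's burial-pattern similarity to the source and
    ``weights`` = 1 - theta_d.
    """

    source: CGSystem
    angles: np.ndarray          # degrees, per decoy
    shifts: np.ndarray          # A, per decoy
    coords: list[np.ndarray]    # full-site coordinate arrays
    theta_d: np.ndarray
    features: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def weights(self) -> np.ndarray:
        return 1.0 - self.theta_d

    def systems(self):
        for c in self.coords:
            yield self.source.with_coords(c)

    def compute_features(self, params: ContactParams, slab: MembraneSlab,
                         scale: HydrophobicityScale) -> np.ndarray:
        self.features = np.array(
            [phi_features(s, params, slab, scale) for s in self.systems()])
        return self.features


def generate_decoys(cg: CGSystem, angles=PAPER_ANGLES, shifts=PAPER_SHIFTS,
                    zm: float = 15.0) -> DecoySet:
    """One decoy per (rotation angle, z shift) grid point.

    Rotation is about the x axis through the CA centroid, applied before the
    vertical shift. Deterministic in its arguments.
    """
    angles = np.asarray(list(angles), dtype=float)
    shifts = np.asarray(list(shifts), dtype=float)
    if angles.size == 0 or shifts.size == 0:
        raise ValueError("angle and shift grids must be non-empty")
    center = cg.ca_positions().mean(axis=0)
    coords, thetas, angs, shs = [], [], [], []
    for a in angles:
        rotated = (cg.coords - center) @ _rot_x(a).T + center
        for s in shifts:
            c = rotated + np.array([0.0, 0.0, s])
            decoy = cg.with_coords(c)
            coords.append(c)
            thetas.append(burial_similarity(cg, decoy, zm))
            angs.append(a)
            shs.append(s)
    return DecoySet(cg, np.array(angs), np.array(shs), coords, np.array(thetas))


def phi_features(cg: CGSystem, params: ContactParams, slab: MembraneSlab,
                 scale: HydrophobicityScale) -> tuple[float, float, float]:
    """(phi_wat, phi_mem, phi_memburial) of one structure."""
    phi_wat, phi_mem, _ = contact_components(cg, params, slab)
    return phi_wat, phi_mem, membrane_burial_energy(cg, scale, slab)


def weighted_decoy_average(values, theta_d) -> float:
    """<phi>_mg: decoy average weighted by burial dissimilarity 1 - theta_d."""
    values = np.asarray(values, dtype=float)
    w = 1.0 - np.asarray(theta_d, dtype=float)
    if values.shape[0] != w.shape[0]:
        raise ValueError("values and theta_d must have the same length")
    total = w.sum()
    if total <= 0:
        raise ValueError("all decoys have theta_d = 1; weighted average undefined")
    return float(np.dot(w, values) / total)


def _weighted_moments(e: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    mean = np.dot(w, e) / w.sum()
    var = np.dot(w, (e - mean) ** 2) / w.sum()  # population convention
    return float(mean), float(var)


def z_score(coeffs, native_features, decoy_features, theta_d) -> float:
    """Z = (E_native - <E>_mg) / sigma(E_mg) for coefficients ``coeffs``.

    Decoy mean and standard deviation use the 1 - theta_d weights
    (population variance). Negative Z means a funneled landscape.
    """
    k = np.asarray(coeffs, dtype=float)
    native = float(np.dot(k, np.asarray(native_features, dtype=float)))
    decoys = np.asarray(decoy_features, dtype=float) @ k
    w = 1.0 - np.asarray(theta_d, dtype=float)
    if np.sum(w > 0) < 2:
        raise ValueError("need at least 2 decoys with weight > 0")
    mean, var = _weighted_moments(decoys, w)
    if var <= 0:
        raise ValueError("zero weighted variance of decoy energies; Z undefined")
    return (native - mean) / np.sqrt(var)


@dataclass(frozen=True)
class OptimizationResult:
    coefficients: tuple[float, float, float]  # (k_wat, k_mem, k_memburial)
    z: float                                  # mean signed Z at the optimum
    normalization: str = "k_wat=1"
    degenerate: bool = False


def _training_arrays(training, params=None, slab=None, scale=None):
    """Normalize training input to (native_features, decoy_features, theta_d) triples.

    Entries may pair either a precomputed native feature triple or a native
    CGSystem (requires ``params``/``slab``/``scale`` to evaluate phi) with a
    DecoySet or a raw (decoy_features, theta_d) pair.
    """
    out = []
    for native, decoys in training:
        if isinstance(native, CGSystem):
            if params is None or slab is None or scale is None:
                raise ValueError(
                    "training with CGSystem natives needs params, slab and scale")
            native = phi_features(native, params, slab, scale)
        if isinstance(decoys, DecoySet):
            if decoys.features is None:
                if params is None:
                    raise ValueError(
                        "DecoySet.features not computed; call compute_features "
                        "or pass params, slab and scale")
                decoys.compute_features(params, slab, scale)
            out.append((np.asarray(native, float), decoys.features, decoys.theta_d))
        else:
            feats, theta = decoys
            out.append((np.asarray(native, float), np.asarray(feats, float),
                        np.asarray(theta, float)))
    return out


def optimize_coefficients(training, bounds=(0.0, 10.0), grid_step: float = 0.5,
                          params=None, slab=None, scale=None) -> OptimizationResult:
    """Find (1, k_mem, k_memburial) maximizing the mean funneled |Z|.

    ``training`` is a list of (native_feature_triple, DecoySet-or-
    (decoy_features, theta_d)) entries. The objective is the mean over
    entries of -Z (positive for funneled landscapes); a coarse grid scan
    seeds a bounded quasi-Newton polish. When no coefficient choice
    separates natives from decoys (|Z| ~ 0 everywhere) the result is flagged
    degenerate.
    """
    entries = _training_arrays(training, params, slab, scale)
    if not entries:
        raise ValueError("empty training set")
    for native, feats, theta in entries:
        if np.sum((1.0 - theta) > 0) < 2:
            raise ValueError("every training entry needs >= 2 weighted decoys")

    def mean_minus_z(k23) -> float:
        k = np.array([1.0, k23[0], k23[1]])
        zs = []
        for native, feats, theta in entries:
            try:
                zs.append(-z_score(k, native, feats, theta))
            except ValueError:
                return -np.inf  # degenerate variance direction
        return float(np.mean(zs))

    lo, hi = bounds
    grid = np.arange(lo, hi + 1e-9, grid_step)
    best_val, best_k = -np.inf, (lo, lo)
    for k2 in grid:
        for k3 in grid:
            val = mean_minus_z((k2, k3))
            if val > best_val:
                best_val, best_k = val, (k2, k3)

    res = minimize(lambda k: -mean_minus_z(k), x0=np.array(best_k),
                   method="L-BFGS-B", bounds=[(lo, hi), (lo, hi)])
    if np.isfinite(res.fun) and -res.fun >= best_val:
        best_val, best_k = -float(res.fun), tuple(float(v) for v in res.x)

    degenerate = not np.isfinite(best_val) or abs(best_val) < 1e-8
    coeffs = (1.0, float(best_k[0]), float(best_k[1]))
    z = -best_val if np.isfinite(best_val) else 0.0
    return OptimizationResult(coeffs, z=float(z), degenerate=bool(degenerate))


def select_training(candidates, zm: float = 15.0,
                    chi_range=(0.2, 0.8), max_length: int = 2000):
    """Keep structures with membrane fraction chi in [0.2, 0.8] and L <= 2000."""
    lo, hi = chi_range
    kept = []
    for cg in candidates:
        if cg.L > max_length:
            continue
        chi = chi_fraction(cg, zm)
        if lo <= chi <= hi:
            kept.append(cg)
    return kept
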