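"""Membrane-depth-dependent contact potential and membrane burial energy.

The contact energy of a residue pair interpolates between a water-mediated
well depth and a membrane(lipid)-mediated well depth according to how deeply
both partners sit inside an implicit membrane slab:

    V_contact(i,j) = (1 - a_i a_j) V_water(i,j) + k_relative a_i a_j V_membrane(i,j)
    a_i = 1/2 [tanh(eta (z_i + b)) + tanh(eta (b - z_i))]

with z_i the CA height of residue i above the membrane midplane, b = 15 A and
eta = 1 / A. Each environment's V(i,j) is a two-well potential: a direct well
(4.5-6.5 A between side-chain sites) and a mediated well (6.5-9.5 A) whose
depth switches between a water-mediated and a protein-mediated matrix with
the local residue density around the pair. A separate burial term sums
per-residue octanol-scale hydrophobicities over a smooth indicator of the
slab, Theta(z) = 1/2 tanh[k_m (z + zm)] + 1/2 tanh[k_m (zm - z)].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

from .cg_model import AMINO_ACIDS, CGSystem, MembraneSlab

__all__ = [
    "ContactParams",
    "HydrophobicityScale",
    "PairBreakdown",
    "alpha_membrane",
    "burial_switch",
    "interaction_well",
    "local_density",
    "pair_contact_energy",
    "contact_energy_z",
    "contact_components",
    "membrane_burial_energy",
    "load_gamma_matrix",
    "save_gamma_matrix",
]

_AA_INDEX = {aa: k for k, aa in enumerate(AMINO_ACIDS)}


def _check_gamma(m) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (20, 20):
        raise ValueError(f"interaction matrix must be 20x20, got {m.shape}")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("interaction matrix must be symmetric")
    return m


@dataclass(frozen=True)
class ContactParams:
    """Well-depth matrices and switching parameters of the contact term.

    The six 20x20 matrices are dimensionless well depths indexed by the
    alphabetical one-letter amino-acid order ACDEFGHIKLMNPQRSTVWY: a direct
    matrix, a protein-mediated (high-density) matrix and a water-mediated
    (low-density) matrix, for the water and the membrane environment each.
    """

    gamma_direct_wat: np.ndarray
    gamma_protein_wat: np.ndarray
    gamma_water_wat: np.ndarray
    gamma_direct_mem: np.ndarray
    gamma_protein_mem: np.ndarray
    gamma_water_mem: np.ndarray
    r_min_I: float = 4.5
    r_max_I: float = 6.5
    r_min_II: float = 6.5
    r_max_II: float = 9.5
    eta_c: float = 5.0     # 1/A, steepness of the distance wells
    rho_0: float = 2.6     # density threshold of the mediated switch
    eta_sigma: float = 7.0  # steepness of the density switch
    k_relative: float = 1.0

    def __post_init__(self):
        for name in ("gamma_direct_wat", "gamma_protein_wat", "gamma_water_wat",
                     "gamma_direct_mem", "gamma_protein_mem", "gamma_water_mem"):
            object.__setattr__(self, name, _check_gamma(getattr(self, name)))
        if not (self.r_min_I < self.r_max_I and self.r_min_II < self.r_max_II):
            raise ValueError("well boundaries must satisfy r_min < r_max")
        if self.k_relative < 0:
            raise ValueError("k_relative must be non-negative")

    # -- constructors ------------------------------------------------------
    @classmethod
    def uniform(cls, value: float = 1.0, **kw) -> "ContactParams":
        """All six matrices filled with one value (mainly for tests)."""
        m = np.full((20, 20), float(value))
        return cls(m, m, m, m, m, m, **kw)

    @classmethod
    def direct_only(cls, value: float = 1.0, **kw) -> "ContactParams":
        """Direct wells only; mediated depths zero."""
        m = np.full((20, 20), float(value))
        z = np.zeros((20, 20))
        return cls(m, z, z, m, z, z, **kw)

    @classmethod
    def random_symmetric(cls, rng: np.random.Generator, scale: float = 1.0,
                         **kw) -> "ContactParams":
        """Six independent random symmetric matrices (test scaffolding)."""
        def sym():
            a = rng.normal(scale=scale, size=(20, 20))
            return (a + a.T) / 2
        return cls(sym(), sym(), sym(), sym(), sym(), sym(), **kw)

    @classmethod
    def from_files(cls, direct_wat, protein_wat, water_wat,
                   direct_mem, protein_mem, water_mem, **kw) -> "ContactParams":
        return cls(*(load_gamma_matrix(p) for p in
                     (direct_wat, protein_wat, water_wat,
                      direct_mem, protein_mem, water_mem)), **kw)

    def with_k_relative(self, k: float) -> "ContactParams":
        return replace(self, k_relative=k)

    def index(self, residue_type: str) -> int:
        return _AA_INDEX[residue_type]


def load_gamma_matrix(path) -> np.ndarray:
    """Read a whitespace-delimited 20x20 matrix; '#' lines are comments."""
    return _check_gamma(np.loadtxt(path, comments="#"))


def save_gamma_matrix(matrix, path, header: str | None = None) -> None:
    header = header or (
        "20x20 residue-pair well depths; row/column order " + AMINO_ACIDS
    )
    np.savetxt(path, _check_gamma(matrix), fmt="%12.6f", header=header)


class HydrophobicityScale:
    """Per-residue transfer free energies in kcal/mol (octanol scale).

    Negative values mark residues that prefer the membrane interior; the
    burial energy rewards placing them inside the slab.
    """

    def __init__(self, values: dict[str, float]):
        missing = set(AMINO_ACIDS) - set(values)
        if missing:
            raise ValueError(f"scale is missing residue types: {sorted(missing)}")
        self.values = {aa: float(values[aa]) for aa in AMINO_ACIDS}

    def __getitem__(self, aa: str) -> float:
        return self.values[aa]

    def as_array(self) -> np.ndarray:
        return np.array([self.values[aa] for aa in AMINO_ACIDS])

    @classmethod
    def from_tsv(cls, path) -> "HydrophobicityScale":
        values = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            aa, val = line.split("\t")[:2]
            values[aa] = float(val)
        return cls(values)

    @classmethod
    def wimley_white_octanol(cls) -> "HydrophobicityScale":
        """The packaged Wimley-White octanol transfer scale."""
        ref = resources.files("cgmem") / "data" / "wimley_white_octanol.tsv"
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)

    @classmethod
    def uniform(cls, value: float = 0.0) -> "HydrophobicityScale":
        return cls({aa: value for aa in AMINO_ACIDS})


# ---------------------------------------------------------------------------
# switching functions
# ---------------------------------------------------------------------------

def alpha_membrane(z, slab: MembraneSlab = MembraneSlab()):
    """Smooth membrane-interior indicator of a CA height z (vectorized).

    1 deep inside the slab, 1/2 at |z| = b, 0 far outside; even in z.
    """
    z = np.asarray(z, dtype=float)
    out = 0.5 * (np.tanh(slab.eta * (z + slab.b)) + np.tanh(slab.eta * (slab.b - z)))
    return float(out) if out.ndim == 0 else out


def burial_switch(z, zm: float = 15.0, k_m: float = 1.0):
    """Smooth indicator of the burial slab |z| < zm (vectorized, even in z)."""
    z = np.asarray(z, dtype=float)
    out = 0.5 * np.tanh(k_m * (z + zm)) + 0.5 * np.tanh(k_m * (zm - z))
    return float(out) if out.ndim == 0 else out


def interaction_well(r, r_min: float, r_max: float, eta: float):
    """Smooth distance window: ~1 inside [r_min, r_max], ~0 outside."""
    r = np.asarray(r, dtype=float)
    out = 0.25 * (1 + np.tanh(eta * (r - r_min))) * (1 + np.tanh(eta * (r_max - r)))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# densities and pair energies
# ---------------------------------------------------------------------------

def _pair_masks(cg: CGSystem):
    """Eligibility masks over the residue-pair matrix.

    density pairs: sequence separation >= 2, all interchain pairs;
    contact pairs: sequence separation > 9, all interchain pairs.
    """
    seqpos = cg.res_seqpos
    chain = cg.res_chain_code
    sep = np.abs(seqpos[:, None] - seqpos[None, :])
    same_chain = chain[:, None] == chain[None, :]
    interchain = ~same_chain
    density = (same_chain & (sep >= 2)) | interchain
    contact = (same_chain & (sep > 9)) | interchain
    np.fill_diagonal(density, False)
    np.fill_diagonal(contact, False)
    return density, contact


def _cb_distance_matrix(cg: CGSystem) -> np.ndarray:
    cb = cg.cb_positions()
    d = cb[:, None, :] - cb[None, :, :]
    return np.sqrt(np.sum(d * d, axis=-1))


def local_density(cg: CGSystem, i: int | None = None,
                  params: ContactParams | None = None) -> np.ndarray | float:
    """Residue density rho_i: direct-well window summed over neighbors.

    Neighbors are residues at sequence separation >= 2 (every interchain pair
    counts); distances are between side-chain (CB) sites. With ``i`` given,
    returns rho for that residue only; otherwise the full length-L vector.
    """
    params = params or ContactParams.uniform()
    r = _cb_distance_matrix(cg)
    density_mask, _ = _pair_masks(cg)
    theta = interaction_well(r, params.r_min_I, params.r_max_I, params.eta_c)
    rho = np.sum(np.where(density_mask, theta, 0.0), axis=1)
    return rho if i is None else float(rho[i])


def _sigma_water(rho: np.ndarray, params: ContactParams) -> np.ndarray:
    """Per-residue low-density (water-exposed) weight in [0, 1]."""
    return 0.5 * (1 + np.tanh(params.eta_sigma * (params.rho_0 - rho)))


def _env_matrices(params: ContactParams, env: str):
    if env == "water":
        return params.gamma_direct_wat, params.gamma_protein_wat, params.gamma_water_wat
    if env == "membrane":
        return params.gamma_direct_mem, params.gamma_protein_mem, params.gamma_water_mem
    raise ValueError(f"unknown environment {env!r}; expected 'water' or 'membrane'")


def pair_contact_energy(cg: CGSystem, i: int, j: int, env: str,
                        params: ContactParams,
                        rho: np.ndarray | None = None) -> float:
    """Single-environment contact energy of one eligible residue pair.

    V_env(i,j) = -gamma_direct[a_i,a_j] Theta_I(r_ij)
                 - Theta_II(r_ij) [s_ij gamma_water[a_i,a_j]
                                   + (1 - s_ij) gamma_protein[a_i,a_j]]

    where s_ij = s_i s_j is the product of the partners' low-density weights.
    """
    sep = cg.sequence_separation(i, j)
    if sep is not None and sep <= 9:
        raise ValueError(
            f"residue pair ({i}, {j}) has sequence separation {sep}; "
            "contact pairs need separation > 9 or different chains"
        )
    g_direct, g_protein, g_water = _env_matrices(params, env)
    if rho is None:
        rho = local_density(cg, params=params)
    sig = _sigma_water(rho, params)
    r = float(np.linalg.norm(cg.cb_positions()[i] - cg.cb_positions()[j]))
    ai, aj = _AA_INDEX[cg.res_types[i]], _AA_INDEX[cg.res_types[j]]
    theta_I = interaction_well(r, params.r_min_I, params.r_max_I, params.eta_c)
    theta_II = interaction_well(r, params.r_min_II, params.r_max_II, params.eta_c)
    s_ij = sig[i] * sig[j]
    mediated = s_ij * g_water[ai, aj] + (1 - s_ij) * g_protein[ai, aj]
    return float(-g_direct[ai, aj] * theta_I - theta_II * mediated)


@dataclass
class PairBreakdown:
    """Per-pair decomposition of the z-dependent contact sum."""

    i: np.ndarray            # residue-table indices
    j: np.ndarray
    r: np.ndarray            # CB-CB distance, A
    v_water: np.ndarray      # single-environment energies
    v_membrane: np.ndarray
    alpha_weight: np.ndarray  # a_i a_j of each pair
    v_contact: np.ndarray    # combined, with k_relative applied


def _pair_energies_vectorized(cg: CGSystem, params: ContactParams):
    """Water and membrane pair-energy matrices over eligible contact pairs."""
    r = _cb_distance_matrix(cg)
    density_mask, contact_mask = _pair_masks(cg)
    theta = interaction_well(r, params.r_min_I, params.r_max_I, params.eta_c)
    rho = np.sum(np.where(density_mask, theta, 0.0), axis=1)
    sig = _sigma_water(rho, params)

    aa = np.array([_AA_INDEX[t] for t in cg.res_types])
    ai, aj = np.meshgrid(aa, aa, indexing="ij")
    theta_II = interaction_well(r, params.r_min_II, params.r_max_II, params.eta_c)
    s_ij = sig[:, None] * sig[None, :]

    def env_energy(g_direct, g_protein, g_water):
        mediated = s_ij * g_water[ai, aj] + (1 - s_ij) * g_protein[ai, aj]
        return -g_direct[ai, aj] * theta - theta_II * mediated

    v_wat = env_energy(params.gamma_direct_wat, params.gamma_protein_wat,
                       params.gamma_water_wat)
    v_mem = env_energy(params.gamma_direct_mem, params.gamma_protein_mem,
                       params.gamma_water_mem)
    return r, contact_mask, v_wat, v_mem, rho


def contact_components(cg: CGSystem, params: ContactParams,
                       slab: MembraneSlab = MembraneSlab()):
    """(phi_wat, phi_mem, breakdown): the two z-weighted contact sums.

    phi_wat = sum over pairs (1 - a_i a_j) V_water(i,j)
    phi_mem = sum over pairs a_i a_j V_membrane(i,j)

    These are the features the Z-score optimizer trains on; the full contact
    energy is phi_wat + k_relative * phi_mem.
    """
    r, mask, v_wat, v_mem, _ = _pair_energies_vectorized(cg, params)
    z = cg.ca_positions()[:, 2]
    a = alpha_membrane(z, slab)
    aa_w = a[:, None] * a[None, :]

    iu, ju = np.where(np.triu(mask))
    w = aa_w[iu, ju]
    vw, vm = v_wat[iu, ju], v_mem[iu, ju]
    v_pair = (1 - w) * vw + params.k_relative * w * vm
    breakdown = PairBreakdown(iu, ju, r[iu, ju], vw, vm, w, v_pair)
    phi_wat = float(np.sum((1 - w) * vw))
    phi_mem = float(np.sum(w * vm))
    return phi_wat, phi_mem, breakdown


def contact_energy_z(cg: CGSystem, params: ContactParams,
                     slab: MembraneSlab = MembraneSlab()):
    """Total z-dependent contact energy and its per-pair breakdown."""
    if cg.L == 0:
        raise ValueError("system has no protein residues")
    phi_wat, phi_mem, breakdown = contact_components(cg, params, slab)
    return phi_wat + params.k_relative * phi_mem, breakdown


def membrane_burial_energy(cg: CGSystem, scale: HydrophobicityScale,
                           slab: MembraneSlab = MembraneSlab()) -> float:
    """phi_memburial = sum_i A(type_i) Theta(z_i, zm) over protein residues."""
    z = cg.ca_positions()[:, 2]
    try:
        a_values = np.array([scale[t] for t in cg.res_types])
    except KeyError as exc:
        raise ValueError(f"residue type missing from hydrophobicity scale: {exc}")
    return float(np.sum(a_values * burial_switch(z, slab.zm, slab.k_m)))
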