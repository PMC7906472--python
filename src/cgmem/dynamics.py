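"""Energy assembly, forces, and Langevin simulated annealing.

The total potential is a configurable sum of the in-scope terms:
``contact_z`` (membrane-depth-dependent contacts), ``membrane_burial``,
``disulfide``, ``interface`` (protein-DNA) and ``backbone_springs``, a
harmonic CA-CA virtual-bond surrogate (rest length 3.8 A) that stands in for
a full backbone Hamiltonian so that toy chains hold together during
dynamics. Forces are analytic for the disulfide and backbone terms and
central finite differences elsewhere.

Annealing integrates Langevin dynamics with the BAOAB splitting, temperature
interpolated linearly in step number (default 800 K -> 200 K, friction
1/ps, nominal 5 fs steps). Energies are kcal/mol, lengths A, masses amu,
time ps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cg_model import CGSystem, MembraneSlab
from .disulfide import DisulfideParams, disulfide_energy, disulfide_forces
from .interface import (ElectrostaticsParams, ExcludedVolumeParams,
                        interface_energy)
from .membrane_contact import (ContactParams, HydrophobicityScale,
                               contact_energy_z, membrane_burial_energy)

__all__ = [
    "AnnealSchedule",
    "EnergyModel",
    "Trajectory",
    "IntegrationError",
    "total_energy",
    "forces",
    "run_annealing",
    "KB_KCAL",
]

KB_KCAL = 0.0019872041       # kcal / (mol K)
ACC_CONV = 418.4             # (kcal/mol/A) -> amu A / ps^2

TERM_NAMES = ("contact_z", "membrane_burial", "disulfide", "interface",
              "backbone_springs")


class IntegrationError(RuntimeError):
    pass


@dataclass
class EnergyModel:
    """Selects and parameterizes the potential-energy terms.

    Unset (None) term parameter blocks disable the term; ``terms`` may also
    explicitly list the enabled subset.
    """

    contact_params: ContactParams | None = None
    slab: MembraneSlab = field(default_factory=MembraneSlab)
    hydrophobicity: HydrophobicityScale | None = None
    disulfide_params: DisulfideParams | None = None
    es_params: ElectrostaticsParams | None = None
    ev_params: ExcludedVolumeParams | None = None
    backbone_k: float | None = None           # kcal/mol/A^2
    backbone_r0: float = 3.8
    fd_step: float = 1e-5

    def __post_init__(self):
        self._check_terms()

    def _check_terms(self):
        pass

    @classmethod
    def from_terms(cls, terms: dict, **kw) -> "EnergyModel":
        """Build from a name -> parameter-block mapping; unknown names error."""
        unknown = set(terms) - set(TERM_NAMES)
        if unknown:
            raise ValueError(
                f"unknown energy terms {sorted(unknown)}; valid: {TERM_NAMES}")
        model = cls(**kw)
        if "contact_z" in terms:
            model.contact_params = terms["contact_z"]
        if "membrane_burial" in terms:
            model.hydrophobicity = terms["membrane_burial"]
        if "disulfide" in terms:
            model.disulfide_params = terms["disulfide"]
        if "interface" in terms:
            es, ev = terms["interface"]
            model.es_params, model.ev_params = es, ev
        if "backbone_springs" in terms:
            model.backbone_k = float(terms["backbone_springs"])
        return model

    def enabled_terms(self) -> list[str]:
        out = []
        if self.contact_params is not None:
            out.append("contact_z")
        if self.hydrophobicity is not None:
            out.append("membrane_burial")
        if self.disulfide_params is not None:
            out.append("disulfide")
        if self.es_params is not None or self.ev_params is not None:
            out.append("interface")
        if self.backbone_k is not None:
            out.append("backbone_springs")
        return out

    # -- energies ----------------------------------------------------------
    def energy_breakdown(self, cg: CGSystem) -> dict[str, float]:
        terms: dict[str, float] = {}
        if self.contact_params is not None:
            terms["contact_z"], _ = contact_energy_z(cg, self.contact_params, self.slab)
        if self.hydrophobicity is not None:
            terms["membrane_burial"] = membrane_burial_energy(
                cg, self.hydrophobicity, self.slab)
        if self.disulfide_params is not None:
            terms["disulfide"], _ = disulfide_energy(cg, self.disulfide_params)
        if self.es_params is not None or self.ev_params is not None:
            terms["interface"] = interface_energy(
                cg, self.es_params or ElectrostaticsParams(),
                self.ev_params or ExcludedVolumeParams())
        if self.backbone_k is not None:
            terms["backbone_springs"] = self._backbone_energy(cg)
        return terms

    def energy(self, cg: CGSystem) -> float:
        return float(sum(self.energy_breakdown(cg).values()))

    def _backbone_bonds(self, cg: CGSystem):
        """Harmonic bond list: CA-CA virtual bonds (3.8 A) along each chain,
        plus intra-residue CA-CB (1.53 A) and CA-O (2.0 A) tethers so that
        side-chain and carbonyl sites stay attached during toy dynamics."""
        ica = cg.ca_site_indices()
        same_chain = cg.res_chain_code[:-1] == cg.res_chain_code[1:]
        consecutive = np.diff(cg.res_seqpos) == 1
        keep = same_chain & consecutive
        a = list(ica[:-1][keep])
        b = list(ica[1:][keep])
        r0 = [self.backbone_r0] * len(a)
        icb = cg.cb_site_indices()
        io = cg._io
        for n in range(cg.L):
            if icb[n] != ica[n]:
                a.append(ica[n]); b.append(icb[n]); r0.append(1.53)
            if io[n] >= 0:
                a.append(ica[n]); b.append(io[n]); r0.append(2.0)
        return np.array(a, dtype=int), np.array(b, dtype=int), np.array(r0)

    def _backbone_energy(self, cg: CGSystem) -> float:
        a, b, r0 = self._backbone_bonds(cg)
        if len(a) == 0:
            return 0.0
        r = np.linalg.norm(cg.coords[a] - cg.coords[b], axis=1)
        return float(self.backbone_k * np.sum((r - r0) ** 2))

    def _backbone_forces(self, cg: CGSystem) -> np.ndarray:
        f = np.zeros_like(cg.coords)
        a, b, r0 = self._backbone_bonds(cg)
        if len(a) == 0:
            return f
        d = cg.coords[a] - cg.coords[b]
        r = np.linalg.norm(d, axis=1)
        mag = 2.0 * self.backbone_k * (r - r0)
        unit = d / r[:, None]
        np.add.at(f, a, -mag[:, None] * unit)
        np.add.at(f, b, +mag[:, None] * unit)
        return f

    # -- forces ------------------------------------------------------------
    def forces(self, cg: CGSystem) -> np.ndarray:
        """Forces -dV/dx on every site: analytic where available, else FD."""
        f = np.zeros_like(cg.coords)
        if self.disulfide_params is not None:
            f += disulfide_forces(cg, self.disulfide_params)
        if self.backbone_k is not None:
            f += self._backbone_forces(cg)
        fd_model = self._fd_only_model()
        if fd_model is not None:
            f += _finite_difference_forces(fd_model, cg, self.fd_step)
        return f

    def _fd_only_model(self) -> "EnergyModel | None":
        """A copy holding only the terms that lack analytic gradients."""
        if (self.contact_params is None and self.hydrophobicity is None
                and self.es_params is None and self.ev_params is None):
            return None
        return replace(self, disulfide_params=None, backbone_k=None)


def _finite_difference_forces(model: EnergyModel, cg: CGSystem,
                              h: float) -> np.ndarray:
    f = np.zeros_like(cg.coords)
    work = cg.copy()
    for k in range(cg.n_sites):
        for d in range(3):
            x0 = work.coords[k, d]
            work.coords[k, d] = x0 + h
            ep = model.energy(work)
            work.coords[k, d] = x0 - h
            em = model.energy(work)
            work.coords[k, d] = x0
            f[k, d] = -(ep - em) / (2 * h)
    return f


def total_energy(cg: CGSystem, model: EnergyModel):
    """(total, per-term breakdown) under the model's enabled terms."""
    breakdown = model.energy_breakdown(cg)
    return float(sum(breakdown.values())), breakdown


def forces(cg: CGSystem, model: EnergyModel, h: float | None = None) -> np.ndarray:
    if h is not None:
        model = replace(model, fd_step=h)
    return model.forces(cg)


# ---------------------------------------------------------------------------
# Langevin annealing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnealSchedule:
    """Linear-in-step simulated-annealing schedule.

    Temperatures in K, dt in fs, friction in 1/ps. The canonical protocol
    anneals 800 K -> 200 K over 8e6 nominal-5-fs steps; the default n_steps
    here is desk-scale.
    """

    t_start: float = 800.0
    t_end: float = 200.0
    n_steps: int = 100_000
    dt: float = 5.0
    friction: float = 1.0
    seed: int = 0
    stride: int = 1000       # frame-saving interval

    def __post_init__(self):
        if not (self.t_start >= self.t_end > 0):
            raise ValueError("need t_start >= t_end > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def temperature(self, step: int) -> float:
        if self.n_steps == 1:
            return self.t_start
        frac = step / (self.n_steps - 1)
        return self.t_start + (self.t_end - self.t_start) * min(max(frac, 0.0), 1.0)


@dataclass
class Frame:
    step: int
    temperature: float
    coords: np.ndarray
    energies: dict[str, float]
    kinetic: float = 0.0

    @property
    def total_energy(self) -> float:
        """Potential energy of the frame (sum of the enabled terms)."""
        return float(sum(self.energies.values()))

    @property
    def conserved_energy(self) -> float:
        """Potential + kinetic; constant in the frictionless limit."""
        return self.total_energy + self.kinetic


@dataclass
class Trajectory:
    system: CGSystem
    frames: list[Frame] = field(default_factory=list)

    def final_system(self) -> CGSystem:
        return self.system.with_coords(self.frames[-1].coords)

    def coordinate_frames(self) -> list[np.ndarray]:
        return [f.coords for f in self.frames]

    def energy_table(self) -> list[dict]:
        return [
            {"step": f.step, "temperature": f.temperature,
             "total": f.total_energy, **f.energies}
            for f in self.frames
        ]


def run_annealing(cg: CGSystem, schedule: AnnealSchedule, model: EnergyModel,
                  mass: float = 1.0) -> Trajectory:
    """BAOAB Langevin annealing; deterministic for a fixed schedule seed.

    Initial velocities are Maxwell-Boltzmann at t_start. With friction 0 the
    O-step is the identity and the scheme reduces to velocity Verlet (the
    temperature schedule then never enters).
    """
    rng = np.random.default_rng(schedule.seed)
    dt = schedule.dt * 1e-3  # fs -> ps
    gamma = schedule.friction
    x = cg.coords.copy()
    sigma_v0 = np.sqrt(KB_KCAL * schedule.t_start * ACC_CONV / mass)
    v = rng.normal(scale=sigma_v0, size=x.shape)
    work = cg.copy()

    def force_acc(coords):
        work.coords = coords
        return model.forces(work) * ACC_CONV / mass

    traj = Trajectory(cg)
    a = force_acc(x)
    c1 = np.exp(-gamma * dt) if gamma > 0 else 1.0
    for step in range(schedule.n_steps):
        temp = schedule.temperature(step)
        v += 0.5 * dt * a
        x += 0.5 * dt * v
        if gamma > 0:
            sigma_v = np.sqrt(KB_KCAL * temp * ACC_CONV / mass)
            v = c1 * v + np.sqrt(1 - c1 * c1) * sigma_v * rng.normal(size=v.shape)
        x += 0.5 * dt * v
        a = force_acc(x)
        v += 0.5 * dt * a
        if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > 1e6:
            raise IntegrationError(
                f"integration diverged at step {step} (reduce dt or forces)")
        if step % schedule.stride == 0 or step == schedule.n_steps - 1:
            work.coords = x
            kinetic = float(0.5 * mass * np.sum(v * v) / ACC_CONV)
            traj.frames.append(
                Frame(step, temp, x.copy(), model.energy_breakdown(work), kinetic))
    return traj
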