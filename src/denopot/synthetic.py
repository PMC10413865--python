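"""Analytic toy force fields and nonequilibrium conformer sampling.

Real neural-potential training data comes from DFT energies of sampled
conformations.  Here an analytic force field — harmonic bonds and angles
plus Lennard-Jones nonbonded terms — plays the role of the quantum method:
it gives every generated conformation an exact, cheap energy label, so the
full pretrain → fine-tune pipeline can be exercised and checked end to end.

Conformations are drawn around a local energy minimum either by
normal-mode sampling (random displacements along Hessian eigenvectors) or
by an overdamped Langevin chain, mirroring the two standard routes to
nonequilibrium conformer datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize as scipy_minimize

from .systems import AtomicConformation, write_dataset

__all__ = [
    "ToyForceField",
    "SyntheticDatasetSpec",
    "MinimizeResult",
    "toy_energy_forces",
    "minimize",
    "hessian",
    "normal_mode_sample",
    "langevin_sample",
    "random_chain_forcefield",
    "generate_benchmark_suite",
]

# documented parameter ranges for randomly generated chain molecules
KB_RANGE = (50.0, 500.0)     # kcal/mol/Å²
R0_RANGE = (0.9, 1.6)        # Å
KA_RANGE = (20.0, 100.0)     # kcal/mol/rad²
THETA0_RANGE = (1.6, 2.2)    # rad
EPS_LJ_RANGE = (0.05, 0.3)   # kcal/mol
SIGMA_LJ_RANGE = (2.5, 3.5)  # Å
ELEMENTS = (1, 6, 7, 8)      # H, C, N, O


@dataclass
class ToyForceField:
    """Harmonic bonds/angles + Lennard-Jones nonbonded analytic potential.

    ``nonbonded_pairs`` holds the LJ-interacting pairs: by construction all
    atom pairs that do not share a bond or an angle term.
    """

    n_atoms: int
    atomic_numbers: np.ndarray
    bonds: list  # (i, j, k_b, r0)
    angles: list  # (i, j, k, k_a, theta0); j is the vertex
    eps_lj: float
    sigma_lj: float
    nonbonded_pairs: list = field(default_factory=list)

    def __post_init__(self):
        self.atomic_numbers = np.asarray(self.atomic_numbers, dtype=np.int64)
        if self.eps_lj <= 0 or self.sigma_lj <= 0:
            raise ValueError("LJ parameters must be positive")
        for i, j, kb, r0 in self.bonds:
            if kb <= 0 or r0 <= 0:
                raise ValueError("bond constants must be positive")
            if i == j or not (0 <= i < self.n_atoms and 0 <= j < self.n_atoms):
                raise ValueError("invalid bond indices")
        for i, j, k, ka, t0 in self.angles:
            if ka <= 0 or not (0 < t0 < np.pi):
                raise ValueError("angle constants out of range")
            if len({i, j, k}) != 3:
                raise ValueError("angle indices must be distinct")
        if not self.nonbonded_pairs:
            excluded = {frozenset((i, j)) for i, j, *_ in self.bonds}
            for i, j, k, *_ in self.angles:
                excluded |= {frozenset((i, j)), frozenset((j, k)), frozenset((i, k))}
            self.nonbonded_pairs = [
                (i, j)
                for i in range(self.n_atoms)
                for j in range(i + 1, self.n_atoms)
                if frozenset((i, j)) not in excluded
            ]


def toy_energy_forces(ff: ToyForceField, coordinates) -> tuple[float, np.ndarray]:
    """Energy (kcal/mol) and exact analytic forces (kcal/mol/Å).

    E = Σ ½k_b(r−r0)² + Σ ½k_a(θ−θ0)² + Σ 4ε[(σ/r)¹² − (σ/r)⁶]
    Forces are −∇E.
    """
    x = np.asarray(coordinates, dtype=np.float64)
    if x.shape != (ff.n_atoms, 3):
        raise ValueError(f"coordinates shape {x.shape} != ({ff.n_atoms}, 3)")
    if not np.all(np.isfinite(x)):
        raise ValueError("coordinates must be finite")
    energy = 0.0
    forces = np.zeros_like(x)

    for i, j, kb, r0 in ff.bonds:
        d = x[i] - x[j]
        r = np.linalg.norm(d)
        if r == 0.0:
            raise FloatingPointError(f"coincident bonded atoms {i},{j}")
        energy += 0.5 * kb * (r - r0) ** 2
        f = -kb * (r - r0) * d / r  # force on i
        forces[i] += f
        forces[j] -= f

    for i, j, k, ka, t0 in ff.angles:
        u = x[i] - x[j]
        v = x[k] - x[j]
        ru, rv = np.linalg.norm(u), np.linalg.norm(v)
        if ru == 0.0 or rv == 0.0:
            raise FloatingPointError(f"coincident atoms in angle {i},{j},{k}")
        c = np.clip(u @ v / (ru * rv), -1.0, 1.0)
        theta = np.arccos(c)
        energy += 0.5 * ka * (theta - t0) ** 2
        s = np.sqrt(max(1.0 - c * c, 1e-12))
        dE_dtheta = ka * (theta - t0)
        # d(theta)/dx via standard angle-gradient expressions
        dtheta_di = (c * u / ru - v / rv) / (ru * s)
        dtheta_dk = (c * v / rv - u / ru) / (rv * s)
        dtheta_dj = -(dtheta_di + dtheta_dk)
        forces[i] -= dE_dtheta * dtheta_di
        forces[j] -= dE_dtheta * dtheta_dj
        forces[k] -= dE_dtheta * dtheta_dk

    for i, j in ff.nonbonded_pairs:
        d = x[i] - x[j]
        r2 = d @ d
        if r2 == 0.0:
            raise FloatingPointError(f"coincident nonbonded atoms {i},{j}")
        sr2 = ff.sigma_lj**2 / r2
        sr6 = sr2**3
        sr12 = sr6**2
        energy += 4.0 * ff.eps_lj * (sr12 - sr6)
        # dE/dr2 = 4ε(-6 sr12 + 3 sr6)/r2 ; force = -dE/dx = -2 dE/dr2 · d
        coef = 4.0 * ff.eps_lj * (12.0 * sr12 - 6.0 * sr6) / r2
        forces[i] += coef * d
        forces[j] -= coef * d

    return float(energy), forces


@dataclass
class MinimizeResult:
    coordinates: np.ndarray
    converged: bool
    n_steps: int
    max_force: float
    energy: float


def minimize(
    ff: ToyForceField,
    start_coordinates,
    tol: float = 1e-6,
    max_steps: int = 2000,
) -> MinimizeResult:
    """L-BFGS minimization until the max-norm force drops below ``tol``."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    x0 = np.asarray(start_coordinates, dtype=np.float64)

    def fun(flat):
        e, f = toy_energy_forces(ff, flat.reshape(-1, 3))
        if not np.isfinite(e):
            raise FloatingPointError("non-finite energy during minimization")
        return e, -f.ravel()

    if max_steps <= 0:
        e, f = toy_energy_forces(ff, x0)
        mf = float(np.abs(f).max())
        return MinimizeResult(x0, mf < tol, 0, mf, e)

    res = scipy_minimize(
        fun,
        x0.ravel(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_steps, "gtol": tol * 1e-2, "ftol": 1e-14},
    )
    coords = res.x.reshape(-1, 3)
    e, f = toy_energy_forces(ff, coords)
    mf = float(np.abs(f).max())
    return MinimizeResult(coords, mf < tol, int(res.nit), mf, e)


def hessian(ff: ToyForceField, coordinates, step: float = 1e-4) -> np.ndarray:
    """3N×3N Hessian by central finite differences of the analytic forces,
    symmetrized as (H + Hᵀ)/2."""
    x = np.asarray(coordinates, dtype=np.float64)
    n3 = x.size
    H = np.zeros((n3, n3))
    flat = x.ravel().copy()
    for a in range(n3):
        xp = flat.copy()
        xp[a] += step
        xm = flat.copy()
        xm[a] -= step
        _, fp = toy_energy_forces(ff, xp.reshape(-1, 3))
        _, fm = toy_energy_forces(ff, xm.reshape(-1, 3))
        # H[a, :] = d(-F)/dx_a
        H[a] = (fm.ravel() - fp.ravel()) / (2.0 * step)
    return 0.5 * (H + H.T)


def normal_mode_sample(
    ff: ToyForceField,
    minimum_coordinates,
    scale: float,
    count: int,
    rng: np.random.Generator,
    lambda_floor: float = 1e-6,
    max_energy_above_min: float | None = 25.0,
) -> list[AtomicConformation]:
    """Random displacements along non-rigid Hessian eigenmodes.

    Each sample displaces the minimum along every eigenmode q with
    eigenvalue λ_q > ``lambda_floor`` by a coefficient ~ N(0, scale²/λ_q);
    the 6 near-zero rigid-body modes are excluded.  Falls back to Langevin
    sampling for systems too small to have 7 modes.

    The harmonic picture breaks down for large displacements along soft
    modes, where Lennard-Jones terms can produce absurdly high energies
    no curated conformer dataset would contain; draws whose energy exceeds
    the minimum by more than ``max_energy_above_min`` (kcal/mol) are
    rejected and redrawn, shrinking the displacement if rejection persists.
    """
    if scale < 0:
        raise ValueError("scale must be >= 0")
    x0 = np.asarray(minimum_coordinates, dtype=np.float64)
    n3 = x0.size
    if n3 < 7:
        warnings.warn("fewer than 7 modes; falling back to Langevin sampling")
        return langevin_sample(
            ff, x0, step=1e-4, kT=scale**2, burn_in=100, thin=10, count=count, rng=rng
        )
    H = hessian(ff, x0)
    evals, evecs = np.linalg.eigh(H)
    order = np.argsort(np.abs(evals))
    keep = np.ones(n3, dtype=bool)
    keep[order[:6]] = False  # rigid-body translations + rotations
    keep &= evals > lambda_floor
    lam = evals[keep]
    modes = evecs[:, keep]
    e_min, _ = toy_energy_forces(ff, x0)
    out = []
    for s in range(count):
        if scale == 0.0 or lam.size == 0:
            x = x0.copy()
            e, _ = toy_energy_forces(ff, x)
        else:
            amp = scale
            for attempt in range(60):
                c = rng.normal(0.0, amp / np.sqrt(lam))
                x = x0 + (modes @ c).reshape(-1, 3)
                e, _ = toy_energy_forces(ff, x)
                if (
                    max_energy_above_min is None
                    or e <= e_min + max_energy_above_min
                ):
                    break
                if attempt % 10 == 9:
                    amp *= 0.7  # persistent rejection: soften the draw
        out.append(
            AtomicConformation(
                atomic_numbers=ff.atomic_numbers,
                coordinates=x,
                energy=e,
                conformation_id=str(s),
            )
        )
    return out


def langevin_sample(
    ff: ToyForceField,
    start_coordinates,
    step: float,
    kT: float,
    count: int,
    rng: np.random.Generator,
    friction: float = 1.0,
    burn_in: int = 0,
    thin: int = 1,
) -> list[AtomicConformation]:
    """Overdamped Langevin chain: x ← x + (step/γ)·F + √(2·step·kT/γ)·ξ."""
    if step <= 0 or count <= 0:
        raise ValueError("step and count must be positive")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    x = np.asarray(start_coordinates, dtype=np.float64).copy()
    eff = step / friction
    noise_scale = np.sqrt(2.0 * step * kT / friction)
    out = []
    total = burn_in + count * thin
    for t in range(total):
        _, f = toy_energy_forces(ff, x)
        x = x + eff * f + noise_scale * rng.normal(size=x.shape)
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(f"Langevin chain diverged at step {t}")
        if t >= burn_in and (t - burn_in + 1) % thin == 0:
            e, _ = toy_energy_forces(ff, x)
            out.append(
                AtomicConformation(
                    atomic_numbers=ff.atomic_numbers,
                    coordinates=x.copy(),
                    energy=e,
                    conformation_id=str(len(out)),
                )
            )
    return out


# ---------------------------------------------------------------------------
# random benchmark molecules
# ---------------------------------------------------------------------------

def random_chain_forcefield(
    n_atoms: int, rng: np.random.Generator
) -> tuple[ToyForceField, np.ndarray]:
    """A random chain-topology molecule and a reasonable starting geometry.

    Chain topology guarantees a connected interaction graph.  Bond, angle
    and LJ constants are drawn from the documented ranges.
    """
    z = rng.choice(ELEMENTS, size=n_atoms)
    bonds = [
        (i, i + 1, rng.uniform(*KB_RANGE), rng.uniform(*R0_RANGE))
        for i in range(n_atoms - 1)
    ]
    angles = [
        (i, i + 1, i + 2, rng.uniform(*KA_RANGE), rng.uniform(*THETA0_RANGE))
        for i in range(n_atoms - 2)
    ]
    ff = ToyForceField(
        n_atoms=n_atoms,
        atomic_numbers=z,
        bonds=bonds,
        angles=angles,
        eps_lj=rng.uniform(*EPS_LJ_RANGE),
        sigma_lj=rng.uniform(*SIGMA_LJ_RANGE),
    )
    # zig-zag chain respecting bond lengths and angle targets, with a touch
    # of out-of-plane randomness so minimization does not start at a saddle
    x = np.zeros((n_atoms, 3))
    direction = np.array([1.0, 0.0, 0.0])
    for i in range(1, n_atoms):
        r0 = bonds[i - 1][3]
        x[i] = x[i - 1] + direction * r0
        if i < n_atoms - 1:
            t0 = angles[i - 1][4] if i - 1 < len(angles) else 2.0
            ang = np.pi - t0
            rot = np.array(
                [
                    [np.cos(ang), -np.sin(ang), 0.0],
                    [np.sin(ang), np.cos(ang), 0.0],
                    [0.0, 0.0, 1.0],
                ]
            )
            direction = rot @ direction * np.array([1, (-1.0) ** i, 1])
    x += rng.normal(0.0, 0.05, size=x.shape)
    return ff, x


@dataclass
class SyntheticDatasetSpec:
    """Recipe for a packaged synthetic benchmark dataset."""

    n_molecules: int = 20
    atoms_min: int = 5
    atoms_max: int = 9
    conformations_per_molecule: int = 500
    sampler: str = "normal_mode"  # or "langevin"
    nm_scale: float = 0.1  # dimensionless normal-mode amplitude
    nm_max_energy: float = 25.0  # kcal/mol window above the minimum
    langevin_step: float = 1e-4
    langevin_kT: float = 0.3  # kcal/mol-like
    seed: int = 0
    molecule_prefix: str = "mol"

    def __post_init__(self):
        if self.n_molecules < 1 or self.conformations_per_molecule < 1:
            raise ValueError("counts must be >= 1")
        if self.atoms_min < 2 or self.atoms_max < self.atoms_min:
            raise ValueError("invalid atom count range")
        if self.sampler not in ("normal_mode", "langevin"):
            raise ValueError(f"unknown sampler {self.sampler!r}")


def generate_benchmark_suite(
    spec: SyntheticDatasetSpec, directory=None
) -> dict[str, list[AtomicConformation]]:
    """Generate a labeled dataset of nonequilibrium conformations.

    Returns {molecule_id: [conformations]} and, if ``directory`` is given,
    writes the packaged-dataset container there (index.json + XYZ files).
    """
    rng = np.random.default_rng(spec.seed)
    molecules: dict[str, list[AtomicConformation]] = {}
    for m in range(spec.n_molecules):
        n_atoms = int(rng.integers(spec.atoms_min, spec.atoms_max + 1))
        ff, x0 = random_chain_forcefield(n_atoms, rng)
        res = minimize(ff, x0, tol=1e-5, max_steps=5000)
        mid = f"{spec.molecule_prefix}{m:03d}"
        if spec.sampler == "normal_mode":
            confs = normal_mode_sample(
                ff, res.coordinates, spec.nm_scale,
                spec.conformations_per_molecule, rng,
                max_energy_above_min=spec.nm_max_energy,
            )
        else:
            confs = langevin_sample(
                ff, res.coordinates, step=spec.langevin_step, kT=spec.langevin_kT,
                burn_in=200, thin=5, count=spec.conformations_per_molecule, rng=rng,
            )
        for c in confs:
            c.molecule_id = mid
        molecules[mid] = confs
    if directory is not None:
        write_dataset(Path(directory), molecules, seed=spec.seed)
    return molecules
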