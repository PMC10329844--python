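"""Coarse-grained chromosome polymer dynamics driven by RBM positions.

A chromosome is binned into nodes; every node pair interacts through a
12-6 potential V(r) = eps * [(r_m/r)^12 - 2 (r_m/r)^6] whose well depth is
proportional to the summed RBM count of the pair and whose equilibrium
distance follows the dephasing rule

    r_m = c * r_chr * (exp(-r_chr / r_D) + 1 / r_chr)
        = c * (r_chr * exp(-r_chr / r_D) + 1),

with r_chr the backbone separation in node units and r_D the dephasing
distance beyond which the motions of two loci decorrelate. Dynamics are
integrated with velocity Verlet in an NVT ensemble (Anderson thermostat),
confined to a cubic box of edge five times the polymer contour length by a
1/r repulsive wall on all six faces. Contacts accumulated over the
production window give a contact map and a PET-pair-length histogram.

Reduced units throughout (mass = k_B = 1); the printed defaults T = 4000 and
dt = 0.15625 are labels on reduced quantities, not physical kelvin/seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PolymerNode",
    "ForceFieldParams",
    "ForceField",
    "SimState",
    "ContactMap",
    "FitResult",
    "bin_chromosome",
    "pair_well_depth",
    "equilibrium_distance",
    "lj_energy_force",
    "boundary_energy_force",
    "build_force_field",
    "compute_forces",
    "velocity_verlet_step",
    "anderson_thermostat",
    "initialize_state",
    "run_simulation",
    "contact_map",
    "pair_length_distribution",
    "parameter_scan",
    "box_edge",
]


@dataclass(frozen=True)
class PolymerNode:
    index: int
    bp_start: int
    bp_end: int
    rbm_count: int
    mass: float = 1.0


@dataclass(frozen=True)
class ForceFieldParams:
    """All simulator knobs, in reduced units.

    epsilon_scale : well depth contributed per RBM in a node pair.
    r_m_scale     : length constant c of the dephasing rule.
    r_D           : dephasing distance, in nodes (default 10).
    T             : simulation temperature (default 4000).
    dt            : integration step (default 0.15625).
    thermostat_nu : per-step Anderson collision probability per node.
    box_factor    : box edge / polymer contour length (default 5).
    backbone_factor : extra well depth (x epsilon_scale) for adjacent nodes,
                      keeping the chain connected.
    """

    epsilon_scale: float = 4_000.0
    r_m_scale: float = 300.0
    r_D: float = 10.0
    T: float = 4_000.0
    dt: float = 0.15625
    thermostat_nu: float = 0.05
    box_factor: float = 5.0
    boundary_rm: float | None = None      # default r_m_scale
    boundary_eps: float | None = None     # default epsilon_scale
    backbone_factor: float = 10.0
    repulsive_eps: float | None = None    # default epsilon_scale
    cutoff_factor: float = 3.0
    capture_radius: float | None = None   # default 1.5 * r_m_scale
    n_production_steps: int = 10_000
    equil_window: int = 500
    equil_tol: float = 0.02
    max_equil_steps: int = 200_000
    seed: int = 0

    def validate(self) -> "ForceFieldParams":
        for name in ("epsilon_scale", "r_m_scale", "r_D", "T", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.box_factor < 1:
            raise ValueError("box_factor must be >= 1")
        if not 0 <= self.thermostat_nu <= 1:
            raise ValueError("thermostat_nu is a per-step probability")
        return self

    def with_(self, **kw) -> "ForceFieldParams":
        return replace(self, **kw)

    @property
    def boundary_rm_(self) -> float:
        return self.r_m_scale if self.boundary_rm is None else self.boundary_rm

    @property
    def boundary_eps_(self) -> float:
        return self.epsilon_scale if self.boundary_eps is None else self.boundary_eps

    @property
    def repulsive_eps_(self) -> float:
        return self.epsilon_scale if self.repulsive_eps is None else self.repulsive_eps

    @property
    def capture_radius_(self) -> float:
        # the dephasing rule puts even bonded neighbours at ~1.9 c, and
        # mid-range pairs bind at ~4-5 c, so the capture radius must sit at
        # that scale for a bound pair to register as a contact
        return 5.0 * self.r_m_scale if self.capture_radius is None else self.capture_radius


@dataclass
class SimState:
    positions: np.ndarray   # (n, 3)
    velocities: np.ndarray  # (n, 3)
    step: int = 0
    kinetic_energy: float = 0.0
    potential_energy: float = 0.0

    @property
    def total_energy(self) -> float:
        return self.kinetic_energy + self.potential_energy


@dataclass
class ContactMap:
    freq: np.ndarray        # (n, n) in [0, 1], symmetric, diag = 1
    counts: np.ndarray      # (n, n) raw frame counts
    capture_radius: float
    n_frames: int


@dataclass
class FitResult:
    params: dict
    mse: float
    best: bool = False


def bin_chromosome(motifs, chrom_length: int, node_size_bp: int):
    """ceil(chrom_length / node_size) contiguous nodes; a motif belongs to
    the node whose half-open bp range contains its start."""
    if node_size_bp <= 0:
        raise ValueError("node_size_bp must be positive")
    starts = np.asarray(
        motifs["start"] if hasattr(motifs, "columns") else motifs, dtype=np.int64)
    if starts.size and (starts.min() < 0 or starts.max() >= chrom_length):
        raise ValueError("motif outside chromosome bounds")
    n_nodes = int(np.ceil(chrom_length / node_size_bp))
    counts = np.bincount(starts // node_size_bp, minlength=n_nodes)
    return [PolymerNode(i, i * node_size_bp,
                        min((i + 1) * node_size_bp, chrom_length),
                        int(counts[i])) for i in range(n_nodes)]


def pair_well_depth(node_i: PolymerNode, node_j: PolymerNode,
                    epsilon_scale: float, backbone_factor: float = 10.0) -> float:
    """eps = scale * (rbm_i + rbm_j), plus the backbone term for neighbours."""
    eps = epsilon_scale * (node_i.rbm_count + node_j.rbm_count)
    if abs(node_i.index - node_j.index) == 1:
        eps += backbone_factor * epsilon_scale
    return eps


def equilibrium_distance(i: int, j: int, r_m_scale: float, r_D: float) -> float:
    """r_m = c * (r_chr * exp(-r_chr/r_D) + 1), r_chr = |i - j| in nodes."""
    if i == j:
        raise ValueError("equilibrium distance undefined for a node with itself")
    r_chr = abs(i - j)
    return r_m_scale * (r_chr * np.exp(-r_chr / r_D) + 1.0)


def lj_energy_force(r, r_m, eps, cutoff_factor: float = 3.0):
    """12-6 pair energy and radial force magnitude, cutoff-shifted.

    V = eps [(r_m/r)^12 - 2 (r_m/r)^6] - V(r_cut) for r < r_cut = c_f * r_m,
    zero beyond; F = -dV/dr = (12 eps / r) [(r_m/r)^12 - (r_m/r)^6]
    (positive = repulsive, directed along the pair axis).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    a6 = (r_m / r) ** 6
    rc = cutoff_factor * r_m
    shift = eps * ((1.0 / cutoff_factor) ** 12 - 2.0 * (1.0 / cutoff_factor) ** 6)
    inside = r < rc
    v = np.where(inside, eps * (a6 * a6 - 2.0 * a6) - shift, 0.0)
    f = np.where(inside, 12.0 * eps / r * (a6 * a6 - a6), 0.0)
    return v, f


def boundary_energy_force(position, box: float, boundary_rm: float,
                          boundary_eps: float = 1.0):
    """Flat repulsive wall V_B = eps_B * r_m / r_B on each of six faces.

    ``position`` is one 3-vector (or an (n,3) array) inside [0, box]^3;
    returns (energy, force). Forces point inward along each axis.
    """
    pos = np.atleast_2d(np.asarray(position, dtype=float))
    if np.any(pos < 0) or np.any(pos > box):
        raise ValueError("node outside the simulation box")
    r_lo = np.maximum(pos, 1e-12)
    r_hi = np.maximum(box - pos, 1e-12)
    v = boundary_eps * boundary_rm * (1.0 / r_lo + 1.0 / r_hi).sum()
    force = boundary_eps * boundary_rm * (1.0 / r_lo**2 - 1.0 / r_hi**2)
    if np.asarray(position).ndim == 1:
        return float(v), force[0]
    return float(v), force


@dataclass
class ForceField:
    """Precomputed pair matrices for one node chain."""

    eps: np.ndarray          # (n, n) well depths (0 = excluded-volume only)
    r_m: np.ndarray          # (n, n) equilibrium distances
    repulsive_eps: float
    cutoff_factor: float
    box: float
    boundary_rm: float
    boundary_eps: float
    masses: np.ndarray


def box_edge(n_nodes: int, params: ForceFieldParams) -> float:
    """Cubic box edge = box_factor x polymer contour length (n * c)."""
    return params.box_factor * n_nodes * params.r_m_scale


def build_force_field(nodes, params: ForceFieldParams) -> ForceField:
    params.validate()
    rbm = np.array([n.rbm_count for n in nodes], dtype=float)
    masses = np.array([n.mass for n in nodes], dtype=float)
    n = rbm.size
    eps = params.epsilon_scale * (rbm[:, None] + rbm[None, :])
    idx = np.arange(n)
    adj = np.abs(idx[:, None] - idx[None, :]) == 1
    eps[adj] += params.backbone_factor * params.epsilon_scale
    sep = np.abs(idx[:, None] - idx[None, :]).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_m = params.r_m_scale * (sep * np.exp(-sep / params.r_D) + 1.0)
    np.fill_diagonal(eps, 0.0)
    np.fill_diagonal(r_m, params.r_m_scale)
    return ForceField(eps=eps, r_m=r_m, repulsive_eps=params.repulsive_eps_,
                      cutoff_factor=params.cutoff_factor,
                      box=box_edge(n, params),
                      boundary_rm=params.boundary_rm_,
                      boundary_eps=params.boundary_eps_, masses=masses)


def compute_forces(positions: np.ndarray, ff: ForceField):
    """Total force per node and potential energy (pairs + walls).

    Attractive pairs (eps > 0) use the cutoff-shifted 12-6 potential;
    zero-eps pairs keep only the repulsive branch (r < r_m, shifted to 0 at
    r_m) so nodes never overlap.
    """
    n = positions.shape[0]
    dx = positions[:, None, :] - positions[None, :, :]
    r = np.sqrt((dx ** 2).sum(axis=2))
    np.fill_diagonal(r, np.inf)
    if not np.all(np.isfinite(positions)):
        bad = int(np.flatnonzero(~np.isfinite(positions).all(axis=1))[0])
        raise FloatingPointError(f"non-finite position at node {bad}")
    rmin = r.min()
    if rmin <= 0:
        i, j = np.unravel_index(int(np.argmin(r)), r.shape)
        raise FloatingPointError(f"overlapping nodes ({i}, {j})")

    a6 = (ff.r_m / r) ** 6
    attractive = ff.eps > 0
    rc = ff.cutoff_factor * ff.r_m
    shift = ff.eps * ((1.0 / ff.cutoff_factor) ** 12
                      - 2.0 * (1.0 / ff.cutoff_factor) ** 6)
    inside = r < rc
    v_att = np.where(attractive & inside, ff.eps * (a6 * a6 - 2 * a6) - shift, 0.0)
    f_att = np.where(attractive & inside, 12.0 * ff.eps / r * (a6 * a6 - a6), 0.0)

    core = (~attractive) & (r < ff.r_m)
    v_rep = np.where(core, ff.repulsive_eps * (a6 * a6 - 2 * a6) + ff.repulsive_eps, 0.0)
    f_rep = np.where(core, 12.0 * ff.repulsive_eps / r * (a6 * a6 - a6), 0.0)

    fmag = f_att + f_rep
    with np.errstate(invalid="ignore"):
        unit = dx / r[:, :, None]
    forces = (fmag[:, :, None] * unit).sum(axis=1)
    pe_pairs = 0.5 * (v_att + v_rep).sum()

    r_lo = np.maximum(positions, 1e-12)
    r_hi = np.maximum(ff.box - positions, 1e-12)
    pe_wall = ff.boundary_eps * ff.boundary_rm * (1.0 / r_lo + 1.0 / r_hi).sum()
    forces += ff.boundary_eps * ff.boundary_rm * (1.0 / r_lo**2 - 1.0 / r_hi**2)

    if not np.all(np.isfinite(forces)):
        bad = int(np.flatnonzero(~np.isfinite(forces).all(axis=1))[0])
        raise FloatingPointError(f"non-finite force on node {bad}")
    return forces, float(pe_pairs + pe_wall)


def velocity_verlet_step(state: SimState, ff: ForceField, dt: float,
                         forces: np.ndarray | None = None):
    """One velocity-Verlet update (half-kick / drift / half-kick).

    Returns (state, forces) with the forces at the new positions so
    consecutive steps reuse them. Nodes that drift outside the box are
    reflected back in (velocity component flipped) and counted.
    """
    m = ff.masses[:, None]
    if forces is None:
        forces, _ = compute_forces(state.positions, ff)
    v_half = state.velocities + 0.5 * dt * forces / m
    pos = state.positions + dt * v_half

    reflected = 0
    low = pos < 0
    high = pos > ff.box
    if low.any() or high.any():
        reflected = int(low.any(axis=1).sum() + high.any(axis=1).sum())
        pos = np.where(low, -pos, pos)
        pos = np.where(high, 2 * ff.box - pos, pos)
        pos = np.clip(pos, 1e-9, ff.box - 1e-9)
        v_half = np.where(low | high, -v_half, v_half)

    new_forces, pe = compute_forces(pos, ff)
    vel = v_half + 0.5 * dt * new_forces / m
    ke = float(0.5 * (ff.masses[:, None] * vel ** 2).sum())
    new = SimState(positions=pos, velocities=vel, step=state.step + 1,
                   kinetic_energy=ke, potential_energy=pe)
    new.reflected = reflected
    return new, new_forces


def anderson_thermostat(state: SimState, T: float, nu: float,
                        rng: np.random.Generator,
                        masses: np.ndarray | None = None) -> SimState:
    """Resample each node's velocity from Maxwell-Boltzmann(T) w.p. nu."""
    if nu <= 0:
        return state
    n = state.positions.shape[0]
    m = np.ones(n) if masses is None else masses
    hit = rng.random(n) < nu
    if hit.any():
        vel = state.velocities.copy()
        sigma = np.sqrt(T / m[hit])[:, None]
        vel[hit] = rng.normal(size=(int(hit.sum()), 3)) * sigma
        ke = float(0.5 * (m[:, None] * vel ** 2).sum())
        return SimState(state.positions, vel, state.step,
                        ke, state.potential_energy)
    return state


def _relax(pos: np.ndarray, ff: ForceField, n_iter: int = 500,
           max_disp: float | None = None) -> np.ndarray:
    """Capped steepest-descent minimization to defuse steep initial cores.

    A fresh random walk inevitably leaves some non-adjacent pairs inside
    their repulsive range (the equilibrium distance grows with backbone
    separation up to r_D); integrating from there is unstable at any
    sensible dt, so positions are first slid down the gradient with a
    per-iteration displacement cap.
    """
    if max_disp is None:
        max_disp = 0.05 * float(ff.r_m.min())
    f_tol = ff.repulsive_eps / max(float(ff.r_m.min()), 1e-12)
    for _ in range(n_iter):
        forces, _ = compute_forces(pos, ff)
        fmax = float(np.abs(forces).max())
        if fmax < f_tol:
            break
        pos = pos + forces * (max_disp / fmax)
        pos = np.clip(pos, 1e-9, ff.box - 1e-9)
    return pos


def initialize_state(n_nodes: int, ff: ForceField, params: ForceFieldParams,
                     rng: np.random.Generator) -> SimState:
    """Seeded self-avoiding random walk (bond length = the adjacent-pair
    equilibrium distance), relaxed by steepest descent, MB velocities."""
    min_sep = 0.8 * params.r_m_scale
    pos = np.empty((n_nodes, 3))
    pos[0] = ff.box / 2.0
    for i in range(1, n_nodes):
        step_len = float(ff.r_m[i - 1, i])
        for _ in range(200):
            d = rng.normal(size=3)
            d *= step_len / np.linalg.norm(d)
            cand = pos[i - 1] + d
            if np.any(cand < min_sep) or np.any(cand > ff.box - min_sep):
                continue
            if i >= 2 and np.min(np.linalg.norm(pos[:i - 1] - cand, axis=1)) < min_sep:
                continue
            pos[i] = cand
            break
        else:
            # fall back to a slightly shorter step rather than abort
            d = rng.normal(size=3)
            pos[i] = pos[i - 1] + d * (0.9 * step_len / np.linalg.norm(d))
            pos[i] = np.clip(pos[i], min_sep, ff.box - min_sep)
    pos = _relax(pos, ff)
    vel = rng.normal(size=(n_nodes, 3)) * np.sqrt(params.T / ff.masses)[:, None]
    _, pe = compute_forces(pos, ff)
    ke = float(0.5 * (ff.masses[:, None] * vel ** 2).sum())
    return SimState(pos, vel, 0, ke, pe)


def _equilibrated(energies: np.ndarray, window: int, tol: float,
                  ke_scale: float) -> bool:
    """No-drift check on the total-energy series over the last window.

    Instantaneous total energy fluctuates canonically by ~sqrt(2/(3N))
    relative even at equilibrium, so raw fluctuation can never fall below a
    small tolerance. Instead the window is split in half and the halves'
    means compared: equilibrated when their difference is below tol x the
    energy scale plus three standard errors of that difference (estimated
    from block means), i.e. when no drift is detectable beyond noise.
    """
    if energies.size < window:
        return False
    tail = energies[-window:]
    n_blocks = 10
    blocks = tail[: (window // n_blocks) * n_blocks].reshape(n_blocks, -1).mean(axis=1)
    first, second = blocks[: n_blocks // 2], blocks[n_blocks // 2:]
    drift = abs(second.mean() - first.mean())
    se = blocks.std(ddof=1) * np.sqrt(2.0 / (n_blocks // 2))
    scale = max(abs(tail.mean()), ke_scale, 1e-12)
    return drift < tol * scale + 3.0 * se


@dataclass
class SimResult:
    trajectory: np.ndarray      # (n_frames, n, 3) production positions
    energies: pd.DataFrame      # step, kinetic, potential, total
    n_equil_steps: int
    params: ForceFieldParams
    n_reflected: int = 0


def run_simulation(nodes, params: ForceFieldParams,
                   thermostat: bool = True,
                   record_every: int = 1) -> SimResult:
    """Equilibrate until the total-energy drift criterion holds, then record
    ``n_production_steps`` frames. Deterministic given (nodes, params, seed)."""
    params.validate()
    if len(nodes) < 2:
        raise ValueError("need at least two nodes")
    ff = build_force_field(nodes, params)
    rng = np.random.default_rng(params.seed)
    state = initialize_state(len(nodes), ff, params, rng)
    forces, _ = compute_forces(state.positions, ff)

    ke_scale = 1.5 * len(nodes) * params.T
    energies = []
    n_reflected = 0
    step = 0
    while True:
        state, forces = velocity_verlet_step(state, ff, params.dt, forces)
        n_reflected += getattr(state, "reflected", 0)
        if thermostat:
            state = anderson_thermostat(state, params.T, params.thermostat_nu,
                                        rng, ff.masses)
        energies.append(state.total_energy)
        step += 1
        if step >= params.equil_window and step % (params.equil_window // 5) == 0:
            if _equilibrated(np.asarray(energies), params.equil_window,
                             params.equil_tol, ke_scale):
                break
        if step >= params.max_equil_steps:
            raise RuntimeError(
                f"equilibration not reached in {params.max_equil_steps} steps; "
                f"last relative block drift did not fall below {params.equil_tol}")
    n_equil = step

    frames = []
    rows = []
    for i in range(params.n_production_steps):
        state, forces = velocity_verlet_step(state, ff, params.dt, forces)
        n_reflected += getattr(state, "reflected", 0)
        if thermostat:
            state = anderson_thermostat(state, params.T, params.thermostat_nu,
                                        rng, ff.masses)
        if i % record_every == 0:
            frames.append(state.positions.copy())
        rows.append((state.step, state.kinetic_energy,
                     state.potential_energy, state.total_energy))
    energy_df = pd.DataFrame(rows, columns=["step", "kinetic", "potential", "total"])
    return SimResult(np.asarray(frames), energy_df, n_equil, params, n_reflected)


def contact_map(trajectory: np.ndarray, capture_radius: float) -> ContactMap:
    """Fraction of frames with |x_i - x_j| < capture_radius, per node pair."""
    if trajectory.ndim != 3 or trajectory.shape[0] < 1:
        raise ValueError("need at least one trajectory frame")
    n_frames, n, _ = trajectory.shape
    counts = np.zeros((n, n), dtype=np.int64)
    for frame in trajectory:
        dx = frame[:, None, :] - frame[None, :, :]
        r = np.sqrt((dx ** 2).sum(axis=2))
        counts += r < capture_radius
    freq = counts / n_frames
    np.fill_diagonal(freq, 1.0)
    return ContactMap(freq=freq, counts=counts, capture_radius=capture_radius,
                      n_frames=n_frames)


def pair_length_distribution(contacts: ContactMap, node_size_bp: int,
                             bins: np.ndarray | None = None):
    """Normalized histogram of contact genomic spans.

    Every (frame, i<j) contact contributes one event at span
    |i - j| * node_size_bp. Returns (span_bp, probability) arrays summing
    to 1 over the default per-separation bins.
    """
    n = contacts.counts.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    weights = contacts.counts[iu, ju].astype(float)
    if weights.sum() == 0:
        raise ValueError("no contact events")
    seps = (ju - iu) * node_size_bp
    if bins is None:
        grid = np.arange(1, n) * node_size_bp
        hist = np.zeros(grid.size)
        np.add.at(hist, (ju - iu) - 1, weights)
    else:
        grid = 0.5 * (np.asarray(bins)[:-1] + np.asarray(bins)[1:])
        hist, _ = np.histogram(seps, bins=bins, weights=weights)
    return grid, hist / hist.sum()


def parameter_scan(nodes, grid, reference_histogram: np.ndarray,
                   base_params: ForceFieldParams, node_size_bp: int,
                   seed: int = 0):
    """Simulate each grid point and rank by MSE against a reference
    pair-length histogram; best = argmin, ties to the first grid point.

    ``grid`` is a sequence of parameter-override dicts (e.g. r_D, T). Each
    point runs with a seed derived from ``seed`` and the grid index.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("parameter grid is empty")
    ref = np.asarray(reference_histogram, dtype=float)
    results = []
    for gi, overrides in enumerate(grid):
        p = base_params.with_(seed=(seed * 1_000 + gi) % (2**31), **overrides)
        sim = run_simulation(nodes, p)
        cm = contact_map(sim.trajectory, p.capture_radius_)
        _, hist = pair_length_distribution(cm, node_size_bp)
        mse = float(np.mean((hist - ref) ** 2))
        results.append(FitResult(params=dict(overrides), mse=mse))
    best = int(np.argmin([r.mse for r in results]))
    results[best].best = True
    return results
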