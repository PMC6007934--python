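"""Pivot-move Metropolis Monte Carlo, simulated annealing and refinement.

The sampler proposes pivot moves (rigid rotation of one chain arm about a
randomly chosen sugar bead), accepts them with the standard Metropolis
criterion, and anneals from high temperature to the target temperature
using the nonhelical bonded parameter set.  A fixed-temperature
refinement stage re-runs the chain with currently base-paired residues
switched to the helical bonded set.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cg_model import BasePairMap, BeadChain, Sequence, detect_base_pairs, sequence_to_random_chain
from .forcefield import (
    KB,
    EnergyBreakdown,
    EnergyFlags,
    ForceFieldParams,
    IonCondition,
    evaluate_state,
)


@dataclass(frozen=True)
class AnnealSchedule:
    """Cooling schedule: T_start -> T_end (Celsius) in equal steps."""

    T_start_C: float = 130.0
    T_end_C: float = 25.0
    n_temps: int = 22
    steps_per_temp: int = 100_000
    record_interval: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.T_start_C <= self.T_end_C:
            raise ValueError("T_start must exceed T_end")
        if self.n_temps < 1 or self.steps_per_temp <= 0 or self.record_interval <= 0:
            raise ValueError("schedule counts must be positive")

    @property
    def temperatures_C(self) -> np.ndarray:
        if self.n_temps == 1:
            return np.array([self.T_end_C])
        return np.linspace(self.T_start_C, self.T_end_C, self.n_temps)


@dataclass
class Frame:
    """One recorded MC state."""

    step: int
    T: float                    # Kelvin
    energy: EnergyBreakdown
    bpmap: BasePairMap
    coords: np.ndarray | None = None

    @property
    def n_bp(self) -> int:
        return len(self.bpmap)


@dataclass
class Trajectory:
    """Ordered frames from one or more MC runs, plus run metadata."""

    frames: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frames)

    def extend(self, other: "Trajectory"):
        self.frames.extend(other.frames)

    def temperatures(self) -> np.ndarray:
        return np.unique([f.T for f in self.frames])

    def at_temperature(self, T: float, atol: float = 1e-6) -> "Trajectory":
        sel = [f for f in self.frames if abs(f.T - T) <= atol]
        return Trajectory(sel, dict(self.meta))

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for f in self.frames:
            row = {"step": f.step, "T_K": f.T, "T_C": f.T - 273.15,
                   "n_bp": f.n_bp,
                   "pairs": ";".join(f"{i}-{j}" for i, j in f.bpmap.sorted_pairs())}
            row.update(f.energy.as_dict())
            rows.append(row)
        return pd.DataFrame(rows)

    def save(self, path):
        df = self.to_dataframe()
        with open(path, "w") as fh:
            for key, val in self.meta.items():
                fh.write(f"# {key}: {val}\n")
            df.to_csv(fh, sep="\t", index=False)


def pivot_move(chain: BeadChain, rng, theta_max: float = np.pi) -> tuple:
    """Propose a pivot move: rotate one arm rigidly about a random C bead.

    Picks a pivot residue, a side (5' or 3') and a uniform random rotation
    of angle in [-theta_max, theta_max] about a random axis through the
    pivot sugar bead.  Bond lengths inside the rotated arm are preserved
    exactly and the move is reversible with equal proposal density.
    Returns ``(proposed_chain, info)``; the input chain is untouched.
    """
    n = len(chain)
    if n < 3:
        raise ValueError("pivot moves need a chain of length >= 3")
    k = int(rng.integers(n))
    side = int(rng.integers(2))  # 0: rotate 5' arm, 1: rotate 3' arm
    axis = rng.normal(size=3)
    axis /= np.sqrt(axis @ axis)
    angle = float(rng.uniform(-theta_max, theta_max))
    # Rodrigues rotation matrix about the axis
    c, s = np.cos(angle), np.sin(angle)
    K = np.array([[0.0, -axis[2], axis[1]],
                  [axis[2], 0.0, -axis[0]],
                  [-axis[1], axis[0], 0.0]])
    R = np.eye(3) + s * K + (1.0 - c) * (K @ K)
    pivot = chain.coords[k, 1].copy()

    new = chain.copy()
    flat = new.coords.reshape(-1, 3)
    if side == 0:
        sel = slice(0, 3 * k + 1)           # residues < k plus P_k
    else:
        sel = slice(3 * (k + 1), 3 * n)     # residues > k
    flat[sel] = (flat[sel] - pivot) @ R.T + pivot
    return new, {"pivot": k, "side": side, "angle": angle}


def metropolis_accept(delta_U: float, T: float, rng, kB: float = KB) -> bool:
    """Standard Metropolis criterion: accept with min(1, exp(-dU/kB T))."""
    if not np.isfinite(delta_U):
        raise ValueError("delta_U must be finite")
    if delta_U <= 0.0:
        return True
    return bool(rng.random() < np.exp(-delta_U / (kB * T)))


def run_mc(
    chain: BeadChain,
    ion: IonCondition,
    n_steps: int,
    params: ForceFieldParams | None = None,
    flags: EnergyFlags = EnergyFlags(),
    rng=None,
    record_interval: int = 100,
    theta_max: float = np.pi / 2,
    bonded_mode: str = "nonhelical",
    helical_mask=None,
    record_coords: bool = False,
    check_every: int = 10_000,
) -> Trajectory:
    """Fixed-temperature Markov chain; mutates ``chain`` to the final state.

    Frames are recorded at ``record_interval`` (plus the initial state);
    the base-pair map is refreshed after every accepted move.  Every
    ``check_every`` steps the tracked energy is re-derived from scratch and
    asserted against the decomposition identity.
    """
    if params is None:
        params = ForceFieldParams.default()
    if rng is None:
        rng = np.random.default_rng(0)
    energy, bpmap, _ = evaluate_state(chain, ion, params, flags, bonded_mode,
                                      helical_mask)

    traj = Trajectory(meta={"T_K": ion.T, "theta_max": theta_max,
                            "bonded_mode": bonded_mode})
    n_accept = 0

    def record(step):
        # formed pairs are re-detected with the (narrower) reporting window
        traj.frames.append(Frame(
            step, ion.T, energy, detect_base_pairs(chain, params),
            chain.coords.copy() if record_coords else None))

    record(0)
    for step in range(1, n_steps + 1):
        proposal, _ = pivot_move(chain, rng, theta_max)
        new_energy, new_bpmap, _ = evaluate_state(proposal, ion, params, flags,
                                                  bonded_mode, helical_mask)
        if metropolis_accept(new_energy.U_total - energy.U_total, ion.T, rng,
                             params.kB):
            chain.coords[:] = proposal.coords
            energy, bpmap = new_energy, new_bpmap
            n_accept += 1
        if step % record_interval == 0:
            record(step)
        if step % check_every == 0:
            ref, _, _ = evaluate_state(chain, ion, params, flags, bonded_mode,
                                       helical_mask)
            assert abs(ref.U_total - energy.U_total) <= 1e-6 * max(1.0, abs(ref.U_total)), \
                "energy bookkeeping drifted from the decomposition identity"
    traj.meta["acceptance"] = n_accept / n_steps if n_steps else 0.0
    return traj


def anneal(
    seq: Sequence,
    ion: IonCondition,
    schedule: AnnealSchedule,
    params: ForceFieldParams | None = None,
    flags: EnergyFlags = EnergyFlags(),
    record_coords: bool = False,
) -> tuple:
    """Simulated annealing from a random chain; returns (chain, trajectory).

    The ion condition is fixed during cooling; its temperature field is
    overridden by the schedule.  The pivot amplitude is adapted between
    temperature steps toward a 30-50% acceptance window.  Fully
    deterministic for a fixed schedule seed.
    """
    if params is None:
        params = ForceFieldParams.default()
    chain = sequence_to_random_chain(seq, schedule.seed, params)
    rng = np.random.default_rng(schedule.seed + 1)
    theta_max = np.pi / 2
    full = Trajectory(meta={"seed": schedule.seed,
                            "monovalent_mM": ion.monovalent_mM,
                            "divalent_mM": ion.divalent_mM})
    for T_C in schedule.temperatures_C:
        step_ion = IonCondition.from_celsius(T_C, ion.monovalent_mM, ion.divalent_mM)
        traj = run_mc(chain, step_ion, schedule.steps_per_temp, params, flags,
                      rng, schedule.record_interval, theta_max,
                      record_coords=record_coords)
        acc = traj.meta["acceptance"]
        if acc < 0.30:
            theta_max = max(0.02, theta_max * 0.7)
        elif acc > 0.50:
            theta_max = min(np.pi, theta_max * 1.3)
        full.extend(traj)
    return chain, full


def refine(
    chain: BeadChain,
    ion: IonCondition,
    n_steps: int,
    params: ForceFieldParams | None = None,
    rng=None,
    record_interval: int = 100,
    flags: EnergyFlags = EnergyFlags(),
    theta_max: float = 0.3,
) -> tuple:
    """Fixed-temperature refinement with the dual bonded parameter sets.

    Residues base-paired in the input fold use the helical bonded set; the
    label mask is frozen at entry so that transient fraying does not zero
    the helical wells mid-run.  Returns ``(ensemble, trajectory)`` where
    the ensemble holds one BeadChain per recorded frame.
    """
    if params is None:
        params = ForceFieldParams.default()
    if rng is None:
        rng = np.random.default_rng(0)
    entry_map = detect_base_pairs(chain, params,
                                  window=params.pairing["cutoff_offset"])
    mask = np.zeros(len(chain), dtype=bool)
    for i, j in entry_map.pairs:
        mask[i] = mask[j] = True
    traj = run_mc(chain, ion, n_steps, params, flags, rng, record_interval,
                  theta_max, bonded_mode="paired", helical_mask=mask,
                  record_coords=True)
    ensemble = [BeadChain(chain.sequence, f.coords) for f in traj.frames[1:]]
    return ensemble, traj
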