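"""Melting-curve analysis: state fractions, two-state fits, unfolding pathways.

Per-temperature trajectories are classified into F (both stems formed),
S1 / S2 (hairpin intermediates retaining only Stem 1 / Stem 2) and U
(neither stem).  The folded and unfolded fractions are fitted to logistic
two-state transitions,

    f_F(T) = 1 / (1 + exp((T - Tm1)/dT1))
    f_U(T) = 1 - 1 / (1 + exp((T - Tm2)/dT2)),

giving the melting temperatures of the F->I and I->U transitions, and the
denatured-base-pair fraction curve

    f(T) = 1 - [(1 - f_I) f_F(T) + f_I (1 - f_U(T))]

with f_I the denatured fraction at the intermediate-population maximum.
Temperatures at this interface are in Celsius.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .cg_model import BasePairMap, Sequence, StemAnnotation, annotate_stems
from .forcefield import EnergyFlags, ForceFieldParams, IonCondition
from .sampler import AnnealSchedule, Trajectory, anneal, run_mc

STATES = ("F", "S1", "S2", "U")


class ReferenceStemError(ValueError):
    pass


class FitError(RuntimeError):
    def __init__(self, message, residuals=None, p0=None):
        super().__init__(message)
        self.residuals = residuals
        self.p0 = p0


@dataclass
class StateFractions:
    """Fractions of F/S1/S2/U per temperature, with the raw counts."""

    temperatures_C: np.ndarray
    fractions: dict            # state -> array over temperatures
    counts: dict               # state -> integer array over temperatures

    def __post_init__(self):
        total = sum(self.fractions[s] for s in STATES)
        if not np.allclose(total, 1.0, atol=1e-9):
            raise ValueError("state fractions must sum to 1 at every temperature")

    @property
    def f_F(self):
        return self.fractions["F"]

    @property
    def f_U(self):
        return self.fractions["U"]

    @property
    def f_I(self):
        """Single-intermediate view: S1 + S2."""
        return self.fractions["S1"] + self.fractions["S2"]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "T_C": self.temperatures_C,
            "f_F": self.fractions["F"], "f_S1": self.fractions["S1"],
            "f_S2": self.fractions["S2"], "f_U": self.fractions["U"],
        })


@dataclass
class TwoStateFit:
    """Logistic fit parameters for the two unfolding transitions (Celsius)."""

    Tm1: float
    dT1: float
    Tm2: float
    dT2: float
    residuals_F: np.ndarray = field(default_factory=lambda: np.array([]))
    residuals_U: np.ndarray = field(default_factory=lambda: np.array([]))

    def f_F(self, T):
        return logistic_folded(np.asarray(T, dtype=float), self.Tm1, self.dT1)

    def f_U(self, T):
        return 1.0 - logistic_folded(np.asarray(T, dtype=float), self.Tm2, self.dT2)


@dataclass
class MeltingResult:
    """Full melting-scan output: fractions, fits and the f(T) curve."""

    fractions: StateFractions
    fit: TwoStateFit
    f_I: float
    T_grid: np.ndarray
    f_curve: np.ndarray
    dfdT_curve: np.ndarray
    reference_stems: StemAnnotation | None = None

    def summary(self) -> dict:
        return {"Tm1_C": self.fit.Tm1, "dT1_C": self.fit.dT1,
                "Tm2_C": self.fit.Tm2, "dT2_C": self.fit.dT2, "f_I": self.f_I}

    def save(self, path):
        import pandas as pd

        with open(path, "w") as fh:
            for key, val in self.summary().items():
                fh.write(f"# {key}: {val:.6g}\n")
            df = self.fractions.to_dataframe()
            curve = pd.DataFrame({"T_C": self.T_grid, "f": self.f_curve,
                                  "dfdT": self.dfdT_curve})
            df.to_csv(fh, sep="\t", index=False)
            fh.write("\n")
            curve.to_csv(fh, sep="\t", index=False)


def logistic_folded(T, Tm, dT):
    """Two-state folded fraction 1/(1 + exp((T - Tm)/dT))."""
    return 1.0 / (1.0 + np.exp(np.clip((T - Tm) / dT, -500, 500)))


# ---------------------------------------------------------------------------
# state classification
# ---------------------------------------------------------------------------

def reference_stem_sets(reference: StemAnnotation):
    """The two stems of an H-type reference as frozensets of pairs."""
    if reference.n_stems != 2:
        raise ReferenceStemError(
            f"reference structure has {reference.n_stems} stems, not 2; "
            "supply the two stems explicitly for pathway classification")
    s1, s2 = reference.stems
    return frozenset(s1.pairs), frozenset(s2.pairs)


def classify_state(frame_map: BasePairMap, reference: StemAnnotation,
                   threshold: float = 0.5) -> str:
    """Label a frame F, S1, S2 or U against the folded reference stems.

    A stem counts as formed iff at least ``threshold`` of its reference
    pairs are present in the frame (inclusive).
    """
    stem1, stem2 = reference_stem_sets(reference)
    present = set(frame_map.pairs)
    formed1 = len(stem1 & present) >= threshold * len(stem1)
    formed2 = len(stem2 & present) >= threshold * len(stem2)
    if formed1 and formed2:
        return "F"
    if formed1:
        return "S1"
    if formed2:
        return "S2"
    return "U"


def _two_state_labels(frame_map: BasePairMap, reference: StemAnnotation,
                      threshold: float) -> str:
    """F/U labeling against a single-stem (hairpin) reference."""
    (stem,) = reference.stems
    present = set(frame_map.pairs)
    formed = len(frozenset(stem.pairs) & present) >= threshold * len(stem.pairs)
    return "F" if formed else "U"


def state_fractions(
    trajectories: list,
    reference: StemAnnotation,
    threshold: float = 0.5,
    equilibration: float = 0.25,
) -> StateFractions:
    """Classify and tally per-temperature trajectories.

    ``trajectories`` is a list of fixed-temperature Trajectory objects
    (>= 3 temperatures).  The first ``equilibration`` fraction of frames of
    each trajectory is discarded.
    """
    if len(trajectories) < 3:
        raise ValueError("state fractions need >= 3 temperatures")
    if reference.n_stems == 1:
        labeler = lambda m: _two_state_labels(m, reference, threshold)
    else:
        labeler = lambda m: classify_state(m, reference, threshold)
    temps, fracs, counts = [], {s: [] for s in STATES}, {s: [] for s in STATES}
    for traj in trajectories:
        if not traj.frames:
            raise ValueError("empty trajectory")
        skip = int(len(traj.frames) * equilibration)
        frames = traj.frames[skip:] or traj.frames[-1:]
        labels = [labeler(f.bpmap) for f in frames]
        temps.append(frames[0].T - 273.15)
        for s in STATES:
            c = labels.count(s)
            counts[s].append(c)
            fracs[s].append(c / len(labels))
    order = np.argsort(temps)
    return StateFractions(
        np.asarray(temps)[order],
        {s: np.asarray(fracs[s])[order] for s in STATES},
        {s: np.asarray(counts[s], dtype=int)[order] for s in STATES},
    )


# ---------------------------------------------------------------------------
# two-state fitting and the denatured fraction
# ---------------------------------------------------------------------------

def _fit_logistic(T, y, decreasing: bool, bounds_T):
    """Least-squares logistic fit; returns (Tm, dT, residuals)."""
    data = y if decreasing else 1.0 - y
    # initial Tm at the empirical half-crossing
    idx = int(np.argmin(np.abs(data - 0.5)))
    p0 = (float(T[idx]), 5.0)
    lo = (bounds_T[0] - 50.0, 0.1)
    hi = (bounds_T[1] + 50.0, 50.0)
    try:
        popt, _ = curve_fit(logistic_folded, T, data, p0=p0,
                            bounds=(lo, hi), maxfev=20000)
    except RuntimeError as err:
        resid = data - logistic_folded(T, *p0)
        raise FitError(f"two-state fit failed to converge: {err}",
                       residuals=resid, p0=p0) from err
    resid = data - logistic_folded(T, *popt)
    return float(popt[0]), float(popt[1]), resid


def fit_two_state(fractions: StateFractions) -> TwoStateFit:
    """Fit f_F and f_U to independent logistic two-state transitions."""
    T = fractions.temperatures_C
    bounds = (float(T.min()), float(T.max()))
    Tm1, dT1, rF = _fit_logistic(T, fractions.f_F, True, bounds)
    Tm2, dT2, rU = _fit_logistic(T, fractions.f_U, False, bounds)
    return TwoStateFit(Tm1, dT1, Tm2, dT2, rF, rU)


def denatured_fraction(fit: TwoStateFit, f_I: float, T_grid) -> tuple:
    """Denatured-base-pair curve f(T) and its analytic derivative df/dT.

    f = 1 - [(1 - f_I) f_F(T) + f_I (1 - f_U(T))]; the derivative follows
    from the closed-form derivative of the fitted logistics.
    """
    if not 0.0 <= f_I <= 1.0:
        raise ValueError("f_I must lie in [0, 1]")
    T = np.asarray(T_grid, dtype=float)
    fF = fit.f_F(T)
    fU = fit.f_U(T)
    f = 1.0 - ((1.0 - f_I) * fF + f_I * (1.0 - fU))
    # d/dT [1/(1+e^x)] = -e^x/(1+e^x)^2 / dT, x = (T-Tm)/dT
    dfF = -fF * (1.0 - fF) / fit.dT1
    dfU = (1.0 - fU) * fU / fit.dT2
    dfdT = -(1.0 - f_I) * dfF + f_I * dfU
    return f, dfdT


def estimate_fI(fractions: StateFractions, trajectories: list,
                n_bp_folded: int, equilibration: float = 0.25,
                fit: TwoStateFit | None = None) -> float:
    """Denatured-pair fraction at the intermediate-population maximum.

    Finds T* maximizing f_S1 + f_S2 and returns
    1 - <n_bp(T*)> / n_bp(folded reference).  If the intermediate fraction
    has no interior maximum, falls back (with a warning) to the mean
    base-pair fraction at the midpoint of (Tm1, Tm2).
    """
    fI_curve = fractions.f_I
    k = int(np.argmax(fI_curve))
    interior = 0 < k < len(fI_curve) - 1 and fI_curve[k] > 0
    temps = np.array([t.frames[0].T - 273.15 for t in trajectories])
    order = np.argsort(temps)
    temps = temps[order]
    trajs = [trajectories[i] for i in order]
    if interior:
        T_star = fractions.temperatures_C[k]
    else:
        if fit is None:
            fit = fit_two_state(fractions)
        T_star = 0.5 * (fit.Tm1 + fit.Tm2)
        warnings.warn(
            "intermediate fraction has no interior maximum; "
            f"falling back to the (Tm1, Tm2) midpoint {T_star:.1f} C")
    j = int(np.argmin(np.abs(temps - T_star)))
    frames = trajs[j].frames
    skip = int(len(frames) * equilibration)
    frames = frames[skip:] or frames[-1:]
    mean_bp = float(np.mean([f.n_bp for f in frames]))
    return float(np.clip(1.0 - mean_bp / n_bp_folded, 0.0, 1.0))


# ---------------------------------------------------------------------------
# the full melting pipeline
# ---------------------------------------------------------------------------

def melting_scan(
    seq: Sequence,
    ion: IonCondition,
    T_list_C,
    params: ForceFieldParams | None = None,
    flags: EnergyFlags = EnergyFlags(),
    schedule: AnnealSchedule | None = None,
    steps_per_T: int = 20_000,
    record_interval: int = 50,
    threshold: float = 0.5,
    equilibration: float = 0.25,
    protocol: str = "independent",
    seed: int = 0,
    reference_stems: StemAnnotation | None = None,
    initial_chain=None,
) -> MeltingResult:
    """Anneal once, sample each temperature, and run the full analysis.

    ``protocol`` is ``independent`` (fixed-T runs re-started from the
    annealed fold at every temperature; the default) or ``cooling`` (reuse
    the cooling trajectory recorded at each schedule temperature).  An
    explicit ``initial_chain`` (e.g. a previously folded or constructed
    structure) skips the annealing stage and serves as the folded start.
    """
    T_list_C = np.asarray(T_list_C, dtype=float)
    if T_list_C.size < 3:
        raise ValueError("melting scan needs >= 3 temperatures")
    if params is None:
        params = ForceFieldParams.default()
    if schedule is None:
        schedule = AnnealSchedule(steps_per_temp=steps_per_T,
                                  record_interval=record_interval, seed=seed)
    if initial_chain is not None:
        if initial_chain.sequence.residues != seq.residues:
            raise ValueError("initial_chain sequence does not match")
        if protocol == "cooling":
            raise ValueError("the cooling protocol needs the annealing stage")
        folded, cooling = initial_chain.copy(), None
    else:
        folded, cooling = anneal(seq, ion, schedule, params, flags)
    from .cg_model import detect_base_pairs

    folded_map = detect_base_pairs(folded, params)
    reference = reference_stems or annotate_stems(folded_map, len(seq))
    if reference.n_stems not in (1, 2):
        raise ReferenceStemError(
            f"annealed fold has {reference.n_stems} stems; supply "
            "reference_stems explicitly")

    trajectories = []
    if protocol == "cooling":
        for T_C in T_list_C:
            sub = cooling.at_temperature(T_C + 273.15)
            if not sub.frames:
                raise ValueError(f"cooling trajectory has no frames at {T_C} C")
            trajectories.append(sub)
    elif protocol == "independent":
        for rank, T_C in enumerate(T_list_C):
            chain = folded.copy()
            step_ion = IonCondition.from_celsius(T_C, ion.monovalent_mM,
                                                 ion.divalent_mM)
            rng = np.random.default_rng(seed + 1000 + rank)
            trajectories.append(
                run_mc(chain, step_ion, steps_per_T, params, flags, rng,
                       record_interval, theta_max=0.8))
    else:
        raise ValueError(f"unknown protocol {protocol!r}")

    fractions = state_fractions(trajectories, reference, threshold,
                                equilibration)
    fit = fit_two_state(fractions)
    f_I = estimate_fI(fractions, trajectories, n_bp_folded=len(folded_map),
                      equilibration=equilibration, fit=fit)
    T_grid = np.linspace(T_list_C.min(), T_list_C.max(), 200)
    f_curve, dfdT = denatured_fraction(fit, f_I, T_grid)
    return MeltingResult(fractions, fit, f_I, T_grid, f_curve, dfdT, reference)
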