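"""Synthetic fixtures: ideal helices, toy sequences, planted melting data.

Everything the test suite and examples need is generated here from the
force-field parameter file itself (the ideal A-form CG helix template) or
from closed-form three-state melting models with planted parameters, so
the package is fully testable offline.
"""
from __future__ import annotations

import numpy as np

from .cg_model import BasePairMap, BeadChain, Sequence, annotate_stems
from .forcefield import ForceFieldParams
from .sampler import Frame, Trajectory
from .thermo_analysis import STATES, StateFractions, logistic_folded

# Toy sequences --------------------------------------------------------------

#: 10-nt hairpin with a 3-bp GC-rich stem and a 4-nt loop
HAIRPIN_10NT = Sequence("GGGAAAUCCC", name="hairpin10")

#: Minimal H-type pseudoknot (17 nt): Stem 1 pairs residues
#: (0,11),(1,10),(2,9) (GGC:GCC, all Watson-Crick GC) and Stem 2 pairs
#: (6,16),(7,15),(8,14) (AGA:UCU), crossing in sequence -- a true
#: pseudoknot.  Stem 2's 5' strand runs directly into Stem 1's 3' strand
#: (L2 = 0), so the two stems stack into a quasi-continuous helix, with
#: the 2-nt loop A12-A13 bridging the junction as in natural H-types.
#: The stems use different base identities so no nested (non-crossing)
#: register of comparable strength exists.
PSEUDOKNOT_17NT = Sequence("GGCAAAAGAGCCAAUCU", name="toy_pk")

#: tmRNA PK1 pseudoknot sequence (22 nt) used as the realistic fold target
TMRNA_PK1_22NT = Sequence("GGGGUGGCUCCCCUAACAGCCG", name="pk1_22nt")

#: Reference pair sets of the toy pseudoknot
PSEUDOKNOT_STEM1 = ((0, 11), (1, 10), (2, 9))
PSEUDOKNOT_STEM2 = ((6, 16), (7, 15), (8, 14))


def pseudoknot_reference():
    """Reference BasePairMap and StemAnnotation of the 17-nt toy pseudoknot."""
    bpmap = BasePairMap.from_pairs(PSEUDOKNOT_STEM1 + PSEUDOKNOT_STEM2,
                                   len(PSEUDOKNOT_17NT))
    return bpmap, annotate_stems(bpmap, len(PSEUDOKNOT_17NT))


# Ideal helix geometry -------------------------------------------------------

def _template_beads(params: ForceFieldParams):
    t = params.helix_template
    out = {}
    for name, (r, phi_deg, z) in t["cylindrical"].items():
        phi = np.deg2rad(phi_deg)
        out[name] = np.array([r * np.cos(phi), r * np.sin(phi), z])
    return out, t["rise"], np.deg2rad(t["twist_deg"])


def _helix_op(pos: np.ndarray, k: int, twist: float, rise: float) -> np.ndarray:
    c, s = np.cos(k * twist), np.sin(k * twist)
    return np.array([c * pos[0] - s * pos[1],
                     s * pos[0] + c * pos[1],
                     pos[2] + k * rise])


def _dyad(pos: np.ndarray) -> np.ndarray:
    return np.array([pos[0], -pos[1], -pos[2]])


def helix_strand_coords(params: ForceFieldParams, axis_indices,
                        strand: int = 1) -> np.ndarray:
    """(len, 3, 3) template coordinates for residues at given axis positions.

    ``strand=1`` is the reference strand; ``strand=2`` is its dyad image
    (the base-paired antiparallel partner at the same axis index).
    """
    beads, rise, twist = _template_beads(params)
    out = np.empty((len(axis_indices), 3, 3))
    for row, k in enumerate(axis_indices):
        for b, name in enumerate(("P", "C", "N")):
            pos = beads[name] if strand == 1 else _dyad(beads[name])
            out[row, b] = _helix_op(pos, k, twist, rise)
    return out


def ideal_helix_chain(seq: Sequence, params: ForceFieldParams | None = None) -> BeadChain:
    """A single strand laid out on the ideal A-form template.

    Its bonded energy under the helical parameter set is at the well
    minimum by construction.
    """
    if params is None:
        params = ForceFieldParams.default()
    coords = helix_strand_coords(params, range(len(seq)))
    return BeadChain(seq, coords)


def ideal_hairpin_chain(stem5: str, loop: str,
                        params: ForceFieldParams | None = None) -> BeadChain:
    """A hairpin whose stem sits exactly on the A-form duplex template.

    The 5' stem strand occupies axis positions 0..L-1, the 3' strand is the
    dyad image running back down, and the loop bridges the two strand ends
    on a smooth arc.  Loop length must be >= 3 so that every stem pair
    satisfies the minimum loop separation.
    """
    if params is None:
        params = ForceFieldParams.default()
    if len(loop) < 3:
        raise ValueError("loop must have >= 3 nucleotides")
    stem3 = _reverse_complement(stem5)
    seq = Sequence(stem5 + loop + stem3, name="ideal_hairpin")
    L, nl = len(stem5), len(loop)
    coords = np.empty((len(seq), 3, 3))
    coords[:L] = helix_strand_coords(params, range(L))
    coords[L + nl:] = helix_strand_coords(params, range(L - 1, -1, -1), strand=2)
    # bridge the loop on a semicircular arc rising above the helix top,
    # from the last 5'-strand sugar to the first 3'-strand phosphate
    a = coords[L - 1, 1]
    b = coords[L + nl, 0]
    mid = 0.5 * (a + b)
    e1 = (b - a) / np.linalg.norm(b - a)
    up = np.array([0.0, 0.0, 1.0])
    e2 = up - np.dot(up, e1) * e1
    e2 /= np.linalg.norm(e2)
    radius = 0.5 * np.linalg.norm(b - a) + 2.0
    prev_c = a
    for k in range(nl):
        theta = np.pi * (1.0 - (k + 1) / (nl + 1))
        c = mid + radius * (np.cos(theta) * e1 + np.sin(theta) * e2)
        out = (c - mid) / np.linalg.norm(c - mid)
        coords[L + k, 1] = c
        coords[L + k, 0] = 0.5 * (prev_c + c) + 2.2 * out
        coords[L + k, 2] = c + 3.445 * out
        prev_c = c
    return BeadChain(seq, coords)


def ideal_pseudoknot_chain(params: ForceFieldParams | None = None) -> BeadChain:
    """The 17-nt toy pseudoknot laid out on coaxially stacked template stems.

    The quasi-continuous strand (Stem 2's 5' side running into Stem 1's 3'
    side, residues 6-11) ascends the helix axis; the two paired segments
    (residues 0-2 and 14-16) are dyad images descending it; loops L1
    (residues 3-5) and the junction loop A12-A13 are bridged on arcs.
    Detection recovers exactly the designed six pairs.
    """
    if params is None:
        params = ForceFieldParams.default()
    n = len(PSEUDOKNOT_17NT)
    coords = np.empty((n, 3, 3))
    # continuous strand: residues 6..11 at axis -1..4
    coords[6:12] = helix_strand_coords(params, range(-1, 5), strand=1)
    # Stem 1's 5' segment: residues 0,1,2 paired to 11,10,9 -> axes 4,3,2
    coords[0:3] = helix_strand_coords(params, [4, 3, 2], strand=2)
    # Stem 2's 3' segment: residues 14,15,16 paired to 8,7,6 -> axes 1,0,-1
    coords[14:17] = helix_strand_coords(params, [1, 0, -1], strand=2)
    _bridge_loop(coords, start_c=coords[2, 1], end_p_anchor=coords[6, 0],
                 residues=(3, 4, 5))
    _bridge_loop(coords, start_c=coords[11, 1], end_p_anchor=coords[14, 0],
                 residues=(12, 13))
    return BeadChain(PSEUDOKNOT_17NT, coords)


def _bridge_loop(coords, start_c, end_p_anchor, residues):
    """Place loop residues on an arc between two anchor beads."""
    a, b = start_c, end_p_anchor
    mid = 0.5 * (a + b)
    e1 = (b - a) / np.linalg.norm(b - a)
    away = mid / max(np.linalg.norm(mid[:2]), 1e-6)
    e2 = np.array([away[0], away[1], 0.0])
    e2 -= np.dot(e2, e1) * e1
    norm = np.linalg.norm(e2)
    if norm < 1e-6:
        e2 = np.array([0.0, 0.0, 1.0]) - e1[2] * e1
        norm = np.linalg.norm(e2)
    e2 /= norm
    radius = 0.5 * np.linalg.norm(b - a) + 2.5
    nl = len(residues)
    prev_c = a
    for k, res in enumerate(residues):
        theta = np.pi * (1.0 - (k + 1) / (nl + 1))
        c = mid + radius * (np.cos(theta) * e1 + np.sin(theta) * e2)
        out = (c - mid) / np.linalg.norm(c - mid)
        coords[res, 1] = c
        coords[res, 0] = 0.5 * (prev_c + c) + 2.2 * out
        coords[res, 2] = c + 3.445 * out
        prev_c = c


def _reverse_complement(s: str) -> str:
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    return "".join(comp[b] for b in reversed(s))


# Planted three-state melting data -------------------------------------------

def three_state_fractions(T_list_C, Tm1: float, dT1: float, Tm2: float,
                          dT2: float, s2_share: float = 0.0) -> StateFractions:
    """Exact state fractions from the planted two-logistic model.

    p_F = f_F(T), p_U = f_U(T), intermediate = remainder split between S1
    and S2 by ``s2_share``.  Round-tripping these fractions through the
    two-state fit recovers the planted parameters to float precision.
    """
    T = np.asarray(T_list_C, dtype=float)
    p_F = logistic_folded(T, Tm1, dT1)
    p_U = 1.0 - logistic_folded(T, Tm2, dT2)
    p_I = np.clip(1.0 - p_F - p_U, 0.0, 1.0)
    # renormalize against clipping artifacts
    total = p_F + p_U + p_I
    p_F, p_U, p_I = p_F / total, p_U / total, p_I / total
    fractions = {"F": p_F, "U": p_U,
                 "S1": (1.0 - s2_share) * p_I, "S2": s2_share * p_I}
    counts = {s: np.round(fractions[s] * 10_000).astype(int) for s in STATES}
    return StateFractions(T, fractions, counts)


def three_state_trajectories(
    T_list_C,
    Tm1: float, dT1: float, Tm2: float, dT2: float,
    frames_per_T: int = 400,
    s2_share: float = 0.3,
    seed: int = 0,
    reference_pairs=(PSEUDOKNOT_STEM1, PSEUDOKNOT_STEM2),
    n: int = len(PSEUDOKNOT_17NT),
) -> list:
    """Sampled per-temperature trajectories with planted state labels.

    Each frame carries the base-pair map of its sampled state (F: both
    stems, S1/S2: one stem, U: none), so downstream classification,
    fraction tallies and f_I estimation can be checked against the ground
    truth.  Returns a list of Trajectory objects, one per temperature.
    """
    rng = np.random.default_rng(seed)
    stem1, stem2 = reference_pairs
    maps = {
        "F": BasePairMap.from_pairs(tuple(stem1) + tuple(stem2), n),
        "S1": BasePairMap.from_pairs(stem1, n),
        "S2": BasePairMap.from_pairs(stem2, n),
        "U": BasePairMap.from_pairs((), n),
    }
    from .forcefield import EnergyBreakdown

    zero = EnergyBreakdown(0, 0, 0, 0, 0, 0, 0, 0)
    out = []
    for T_C in np.asarray(T_list_C, dtype=float):
        p_F = logistic_folded(T_C, Tm1, dT1)
        p_U = 1.0 - logistic_folded(T_C, Tm2, dT2)
        p_I = max(0.0, 1.0 - p_F - p_U)
        probs = np.array([p_F, (1 - s2_share) * p_I, s2_share * p_I, p_U])
        probs /= probs.sum()
        labels = rng.choice(4, size=frames_per_T, p=probs)
        frames = [Frame(step=k, T=T_C + 273.15, energy=zero,
                        bpmap=maps[("F", "S1", "S2", "U")[lab]])
                  for k, lab in enumerate(labels)]
        out.append(Trajectory(frames, {"T_K": T_C + 273.15, "planted": True}))
    return out
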