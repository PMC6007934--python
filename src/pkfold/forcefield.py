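"""Coarse-grained force field: U = Ub + Ua + Ud + Uexc + Ubp + Ubs + Ucs + Uel.

Bonded terms (bond, angle, dihedral) come in two parameter sets:
``nonhelical`` (single strands and loops; drives the folding stage) and
``helical`` (base-paired regions; used during structure refinement).
Nonbonded terms are excluded volume, base pairing, sequence-dependent
base stacking (Turner-style nearest-neighbor dH/dS), coaxial stacking
between stems across short junctions, and screened Debye-Hueckel
electrostatics between phosphates with a Manning counterion-condensation
charge reduction that interpolates between monovalent-only and
divalent-dominated limits.

Units: kcal/mol, Angstrom, Kelvin.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .cg_model import (
    BasePairMap,
    BeadChain,
    StemAnnotation,
    annotate_stems,
    is_complementary,
    pair_type,
)

KB = 0.0019872  # kcal/(mol*K)


def water_dielectric(T: float) -> float:
    """Relative permittivity of water at temperature T (K).

    Empirical polynomial in Celsius (Malmberg-Maryott form); valid over the
    simulated 250-450 K range by mild extrapolation.
    """
    t = T - 273.15
    return 87.740 - 0.40008 * t + 9.398e-4 * t**2 - 1.410e-6 * t**3


class ParameterError(ValueError):
    pass


class ForceFieldParams:
    """All force-field parameters, loaded from a keyed YAML file."""

    def __init__(self, raw: dict, source: str = "<dict>"):
        self.raw = raw
        self.source = source
        self.bead_radii = raw["beads"]["radii"]
        self.phosphate_charge = raw["beads"]["phosphate_charge"]
        self.helix_template = raw["helix_template"]
        self.bonded = raw["bonded"]
        self.excluded_volume = raw["excluded_volume"]
        self.pairing = raw["pairing"]
        self.stacking = raw["stacking"]
        self.coaxial = raw["coaxial"]
        self.electrostatics = raw["electrostatics"]
        self.kB = raw.get("constants", {}).get("kB", KB)
        self._bonded_cache = {}
        self._pair_cache = {}
        self._validate()

    def _validate(self):
        d = self.pairing["depth"]
        if not (d["GC"] >= d["AU"] >= d["GU"]):
            raise ParameterError("pairing depths must satisfy GC >= AU >= GU")
        for r in self.bead_radii.values():
            if r <= 0:
                raise ParameterError("bead radii must be positive")
        for setname in ("helical", "nonhelical"):
            for group in ("bonds", "angles", "dihedrals"):
                for key, (eq, k) in self.bonded[setname][group].items():
                    if k <= 0:
                        raise ParameterError(f"force constant {setname}/{group}/{key} must be > 0")
        # every WC dinucleotide step must resolve in the stacking table
        for a, b in [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")]:
            for c, d2 in [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")]:
                self.stack_step(a + c, d2 + b)

    @classmethod
    def from_file(cls, path) -> "ForceFieldParams":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(raw, source=str(path))

    @classmethod
    def default(cls) -> "ForceFieldParams":
        return _default_params()

    @staticmethod
    def default_path() -> Path:
        return Path(resources.files("pkfold") / "data" / "params.yaml")

    def checksum(self) -> str:
        if self.source != "<dict>":
            data = Path(self.source).read_bytes()
        else:
            data = yaml.safe_dump(self.raw).encode()
        return hashlib.sha256(data).hexdigest()

    # -- lookups ----------------------------------------------------------

    def bead_radii_array(self, seq) -> np.ndarray:
        r = self.bead_radii
        return np.tile([r["P"], r["C"], r["N"]], len(seq))

    def stack_step(self, top: str, bottom: str) -> tuple:
        """(dH, dS) for the dinucleotide step 5'-top-3' / 5'-bottom-3'.

        ``top[0]`` pairs ``bottom[1]`` and ``top[1]`` pairs ``bottom[0]``.
        Steps involving a GU pair fall back to the generic wobble increment.
        """
        table = self.stacking["table"]
        key = f"{top}/{bottom}"
        alt = f"{bottom}/{top}"
        if key in table:
            dh, ds = table[key]
        elif alt in table:
            dh, ds = table[alt]
        else:
            for x, y in ((top[0], bottom[1]), (top[1], bottom[0])):
                if not is_complementary(x, y):
                    raise ParameterError(f"step {key} contains a non-canonical pair")
            dh, ds = self.stacking["gu_step"]
        return dh, ds

    def step_free_energy(self, top: str, bottom: str, T: float) -> float:
        """G(T) = dH - T*dS for a dinucleotide step, kcal/mol."""
        dh, ds = self.stack_step(top, bottom)
        return dh - T * ds * 1e-3


@lru_cache(maxsize=1)
def _default_params() -> ForceFieldParams:
    return ForceFieldParams.from_file(ForceFieldParams.default_path())


@dataclass(frozen=True)
class IonCondition:
    """Solution condition: temperature (K) and ion concentrations (mM)."""

    T: float                    # Kelvin
    monovalent_mM: float        # K+ / Na+ (treated identically)
    divalent_mM: float = 0.0    # Mg2+

    def __post_init__(self):
        if not (250.0 <= self.T <= 450.0):
            raise ValueError(f"temperature {self.T} K outside 250-450 K")
        if self.monovalent_mM <= 0:
            raise ValueError("monovalent concentration must be > 0 mM")
        if self.divalent_mM < 0:
            raise ValueError("divalent concentration must be >= 0 mM")

    @classmethod
    def from_celsius(cls, t_celsius: float, monovalent_mM: float,
                     divalent_mM: float = 0.0) -> "IonCondition":
        return cls(t_celsius + 273.15, monovalent_mM, divalent_mM)

    @property
    def celsius(self) -> float:
        return self.T - 273.15

    def at_temperature(self, T: float) -> "IonCondition":
        return IonCondition(T, self.monovalent_mM, self.divalent_mM)


@dataclass(frozen=True)
class EnergyFlags:
    """Ablation switches for the nonbonded terms."""

    coaxial: bool = True
    electrostatics: bool = True


@dataclass(frozen=True)
class EnergyBreakdown:
    """Per-term energies (kcal/mol); U_total is their sum."""

    U_b: float
    U_a: float
    U_d: float
    U_exc: float
    U_bp: float
    U_bs: float
    U_cs: float
    U_el: float

    @property
    def U_total(self) -> float:
        return (self.U_b + self.U_a + self.U_d + self.U_exc
                + self.U_bp + self.U_bs + self.U_cs + self.U_el)

    def as_dict(self) -> dict:
        return {
            "U_b": self.U_b, "U_a": self.U_a, "U_d": self.U_d,
            "U_exc": self.U_exc, "U_bp": self.U_bp, "U_bs": self.U_bs,
            "U_cs": self.U_cs, "U_el": self.U_el, "U_total": self.U_total,
        }


# ---------------------------------------------------------------------------
# bonded terms
# ---------------------------------------------------------------------------

def _cross(u, v):
    out = np.empty_like(u)
    out[:, 0] = u[:, 1] * v[:, 2] - u[:, 2] * v[:, 1]
    out[:, 1] = u[:, 2] * v[:, 0] - u[:, 0] * v[:, 2]
    out[:, 2] = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
    return out


def _row_norm(u):
    return np.sqrt(np.einsum("ij,ij->i", u, u))


def _angles(a, b, c):
    u = a - b
    v = c - b
    cosang = np.einsum("ij,ij->i", u, v) / (_row_norm(u) * _row_norm(v))
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def _dihedrals(a, b, c, d):
    b1, b2, b3 = b - a, c - b, d - c
    n1 = _cross(b1, b2)
    n2 = _cross(b2, b3)
    m = _cross(n1, b2 / _row_norm(b2)[:, None])
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m, n2)
    return np.arctan2(y, x)


def _param_arrays(params, group, key, owner_mask):
    """Per-interaction (eq, k) arrays selected by the owner residue's label.

    Angle/dihedral equilibria are returned in radians; cached per mask.
    """
    cache = params._bonded_cache
    ck = (group, key, owner_mask.tobytes())
    hit = cache.get(ck)
    if hit is not None:
        return hit
    hel = params.bonded["helical"][group][key]
    non = params.bonded["nonhelical"][group][key]
    eq = np.where(owner_mask, hel[0], non[0])
    k = np.where(owner_mask, hel[1], non[1])
    if group in ("angles", "dihedrals"):
        eq = np.deg2rad(eq)
    if len(cache) < 4096:
        cache[ck] = (eq, k)
    return eq, k


def _bonded_param_pack(params, mask):
    """Per-residue (eq, k) arrays for every bonded interaction, by owner.

    Angles/dihedral equilibria in radians; cached per helical mask.
    """
    ck = ("pack", mask.tobytes())
    hit = params._bonded_cache.get(ck)
    if hit is not None:
        return hit
    pack = []
    for group, key in (("bonds", "PC"), ("bonds", "CP"), ("bonds", "CN"),
                       ("angles", "PCP"), ("angles", "CPC"),
                       ("angles", "PCN"), ("angles", "NCP"),
                       ("dihedrals", "PCPC"), ("dihedrals", "NCPC"),
                       ("dihedrals", "CPCP")):
        hel = params.bonded["helical"][group][key]
        non = params.bonded["nonhelical"][group][key]
        eq = np.where(mask, hel[0], non[0]).astype(np.float64)
        k = np.where(mask, hel[1], non[1]).astype(np.float64)
        if group != "bonds":
            eq = np.deg2rad(eq)
        pack.extend((eq, k))
    pack = tuple(pack)
    if len(params._bonded_cache) < 4096:
        params._bonded_cache[ck] = pack
    return pack


def bonded_energy(chain: BeadChain, helical_mask, params: ForceFieldParams):
    """(U_b, U_a, U_d) with per-residue helical/nonhelical parameter choice.

    Each interaction uses the parameter set of its owner residue: bonds and
    dihedrals are owned by the residue of their 5'-most sugar/backbone atom,
    angles by the residue of their central atom.
    """
    from ._kernels import bonded_kernel

    n = len(chain)
    mask = np.asarray(helical_mask, dtype=bool)
    if mask.shape != (n,):
        raise ValueError("helical_mask must have one label per residue")
    P, C, N = chain.P, chain.C, chain.N

    if bonded_kernel is not None:
        pack = _bonded_param_pack(params, mask)
        return bonded_kernel(np.ascontiguousarray(P),
                             np.ascontiguousarray(C),
                             np.ascontiguousarray(N), *pack)

    # shared difference vectors: d_pc = C-P, d_cn = N-C, d_cp = P(next)-C
    d_pc = C - P
    d_cn = N - C
    d_cp = P[1:] - C[:-1]
    r_pc = _row_norm(d_pc)
    r_cn = _row_norm(d_cn)
    r_cp = _row_norm(d_cp)

    U_b = 0.0
    for key, r, owner in (("PC", r_pc, mask), ("CP", r_cp, mask[:-1]),
                          ("CN", r_cn, mask)):
        eq, k = _param_arrays(params, "bonds", key, owner)
        U_b += float(np.sum(k * (r - eq) ** 2))

    def _ang(u, ru, v, rv):
        cosang = np.einsum("ij,ij->i", u, v) / (ru * rv)
        return np.arccos(np.clip(cosang, -1.0, 1.0))

    U_a = 0.0
    for key, th, owner in (
        ("PCP", _ang(-d_pc[:-1], r_pc[:-1], d_cp, r_cp), mask[:-1]),
        ("CPC", _ang(-d_cp, r_cp, d_pc[1:], r_pc[1:]), mask[1:]),
        ("PCN", _ang(-d_pc, r_pc, d_cn, r_cn), mask),
        ("NCP", _ang(d_cn[:-1], r_cn[:-1], d_cp, r_cp), mask[:-1]),
    ):
        eq, k = _param_arrays(params, "angles", key, owner)
        U_a += float(np.sum(k * (th - eq) ** 2))

    U_d = 0.0
    if n >= 2:
        # dihedrals share the backbone bond b2 = d_cp and its normal planes
        b2u = d_cp / r_cp[:, None]
        n2 = _cross(d_cp, d_pc[1:])          # plane of (b2, C1-P1)
        phi_pcpc = _dihedral_from(d_pc[:-1], d_cp, b2u, n2)
        phi_ncpc = _dihedral_from(-d_cn[:-1], d_cp, b2u, n2)
        specs = [("PCPC", phi_pcpc, mask[:-1]), ("NCPC", phi_ncpc, mask[:-1])]
        if n >= 3:
            n2b = _cross(d_pc[1:-1], d_cp[1:])
            phi_cpcp = _dihedral_from(d_cp[:-1], d_pc[1:-1],
                                      d_pc[1:-1] / r_pc[1:-1, None], n2b)
            specs.append(("CPCP", phi_cpcp, mask[1:-1]))
        for key, phi, owner in specs:
            eq, k = _param_arrays(params, "dihedrals", key, owner)
            U_d += float(np.sum(k * (1.0 - np.cos(phi - eq))))
    return U_b, U_a, U_d


def _dihedral_from(b1, b2, b2u, n2):
    """Dihedral about b2 given precomputed unit b2 and n2 = b2 x b3."""
    n1 = _cross(b1, b2)
    m = _cross(n1, b2u)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m, n2)
    return np.arctan2(y, x)


# ---------------------------------------------------------------------------
# excluded volume
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _exclusion_mask(n: int):
    """Boolean (3n, 3n) mask of pairs excluded from U_exc (1-2 and 1-3)."""
    m = np.zeros((3 * n, 3 * n), dtype=bool)
    idx = np.arange(3 * n)
    m[idx, idx] = True
    pairs = []
    for i in range(n):
        P, C, N = 3 * i, 3 * i + 1, 3 * i + 2
        pairs += [(P, C), (C, N), (P, N)]
        if i + 1 < n:
            Pn, Cn = 3 * (i + 1), 3 * (i + 1) + 1
            pairs += [(C, Pn), (P, Pn), (N, Pn), (C, Cn)]
    for a, b in pairs:
        m[a, b] = m[b, a] = True
    return m


def _exc_pair_arrays(params, n: int):
    """Index arrays (i, j) of non-excluded bead pairs plus their sigma sums."""
    ck = ("exc", n)
    hit = params._pair_cache.get(ck)
    if hit is not None:
        return hit
    excl = _exclusion_mask(n)
    iu = np.triu_indices(3 * n, k=1)
    keep = ~excl[iu]
    i, j = iu[0][keep], iu[1][keep]
    r = params.bead_radii
    radii = np.tile([r["P"], r["C"], r["N"]], n)
    sigma = radii[i] + radii[j]
    params._pair_cache[ck] = (i, j, sigma)
    return i, j, sigma


def excluded_volume_energy(chain: BeadChain, params: ForceFieldParams) -> float:
    """Purely repulsive soft-sphere term; zero beyond bead-radius contact."""
    from ._kernels import excluded_kernel

    eps = params.excluded_volume["epsilon"]
    pos = chain.flat
    i, j, sigma = _exc_pair_arrays(params, len(chain))
    if excluded_kernel is not None:
        return float(excluded_kernel(np.ascontiguousarray(pos), i, j, sigma,
                                     eps))
    diff = pos[i] - pos[j]
    d2 = np.einsum("ij,ij->i", diff, diff)
    sel = d2 < sigma * sigma
    if not np.any(sel):
        return 0.0
    x = (sigma[sel] * sigma[sel] / d2[sel]) ** 3
    return float(eps * np.sum(x * x - 2.0 * x + 1.0))


# ---------------------------------------------------------------------------
# base pairing / stacking / coaxial stacking
# ---------------------------------------------------------------------------

def _pair_geometry(chain, i, j, params):
    from .cg_model import antiparallel_factor, backbone_tangents

    p = params.pairing
    d = float(np.linalg.norm(chain.N[i] - chain.N[j]))
    if abs(d - p["r0"]) > p["cutoff_offset"]:
        return 0.0
    u = chain.N[i] - chain.C[i]
    v = chain.N[j] - chain.C[j]
    facing = -float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    g_or = min(1.0, max(0.0, facing / p["orientation_ref"]))
    g_d = np.exp(-((d - p["r0"]) ** 2) / (2.0 * p["sigma"] ** 2))
    t = backbone_tangents(chain)
    g_ap = float(antiparallel_factor(float(np.dot(t[i], t[j])), p))
    return g_d * g_or * g_ap


def pairing_energy(chain: BeadChain, bpmap: BasePairMap,
                   params: ForceFieldParams) -> float:
    """Distance-and-orientation pairing wells, depth by pair class."""
    seq = chain.sequence.residues
    U = 0.0
    for i, j in bpmap.sorted_pairs():
        if not is_complementary(seq[i], seq[j]):
            raise ValueError(f"pair ({i}, {j}) = {seq[i]}-{seq[j]} is not complementary")
        depth = params.pairing["depth"][pair_type(seq[i], seq[j])]
        U -= depth * _pair_geometry(chain, i, j, params)
    return U


def _stack_modulation(chain, pair_a, pair_b, params, section):
    """Gaussian factor in the distance between two base-pair centroids."""
    s = params.raw[section]
    m1 = 0.5 * (chain.N[pair_a[0]] + chain.N[pair_a[1]])
    m2 = 0.5 * (chain.N[pair_b[0]] + chain.N[pair_b[1]])
    d = float(np.linalg.norm(m1 - m2))
    if abs(d - s["r0"]) > s["cutoff_offset"]:
        return 0.0
    return float(np.exp(-((d - s["r0"]) ** 2) / (2.0 * s["sigma"] ** 2)))


def stacking_energy(chain: BeadChain, bpmap: BasePairMap, ion: IonCondition,
                    params: ForceFieldParams) -> float:
    """Nearest-neighbor stacking between adjacent pairs inside stems.

    Each formed dinucleotide step (i,j)/(i+1,j-1) contributes
    G(T) = dH - T*dS from the nearest-neighbor table, modulated by the
    geometric proximity of the two pair centroids.
    """
    seq = chain.sequence.residues
    scale = params.stacking.get("scale", 1.0)
    U = 0.0
    for i, j in bpmap.sorted_pairs():
        if (i + 1, j - 1) in bpmap:
            G = params.step_free_energy(seq[i] + seq[i + 1],
                                        seq[j - 1] + seq[j], ion.T)
            U += scale * G * _stack_modulation(chain, (i, j), (i + 1, j - 1),
                                               params, "stacking")
    return U


def coaxial_energy(chain: BeadChain, stems: StemAnnotation, ion: IonCondition,
                   params: ForceFieldParams, enabled: bool = True) -> float:
    """End-on stacking of two stems across a junction of <= 1 nt.

    The strength is the nearest-neighbor G(T) of the pseudo-step formed by
    the two interfaced base pairs, scaled by ``coaxial.scale`` and the same
    centroid-proximity factor as intrahelix stacking.
    """
    if not enabled or not params.coaxial["enabled"] or stems.n_stems < 2:
        return 0.0
    seq = chain.sequence.residues
    U = 0.0
    min_len = params.coaxial.get("min_helix_length", 2)
    max_gap = params.coaxial["max_junction_loop"]
    slist = [s for s in stems.stems if s.length >= min_len]
    for a in range(len(slist)):
        for b in range(a + 1, len(slist)):
            # an H-type junction can lie on either side of the two stems;
            # evaluate every end-pair combination bridged by <= max_gap
            # unpaired nucleotides and keep the best (most stabilizing)
            # geometric stack -- only one interface can stack at a time
            best = 0.0
            for pa in (slist[a].pairs[0], slist[a].pairs[-1]):
                for pb in (slist[b].pairs[0], slist[b].pairs[-1]):
                    gap = min(abs(x - y) for x in pa for y in pb) - 1
                    if gap > max_gap:
                        continue
                    top = seq[pa[0]] + seq[pb[0]]
                    bottom = seq[pb[1]] + seq[pa[1]]
                    try:
                        G = params.step_free_energy(top, bottom, ion.T)
                    except ParameterError:
                        continue
                    val = (params.coaxial["scale"] * G
                           * _stack_modulation(chain, pa, pb, params,
                                               "coaxial"))
                    best = min(best, val)
            U += best
    return U


def _junction(stem_a, stem_b) -> int:
    from .cg_model import _junction_length
    return _junction_length(stem_a, stem_b)


# ---------------------------------------------------------------------------
# electrostatics
# ---------------------------------------------------------------------------

def bjerrum_length(T: float, params: ForceFieldParams | None = None) -> float:
    """Bjerrum length (A) in water at temperature T (K)."""
    if params is None:
        params = ForceFieldParams.default()
    return params.electrostatics["bjerrum_const"] / (water_dielectric(T) * T)


def debye_length(ion: IonCondition, params: ForceFieldParams | None = None) -> float:
    """Debye screening length (A).

    Ionic strength I = c1 + w*c2 (molar), the divalent species counted with
    its charge-squared weight w (default 3); the water dielectric is
    temperature dependent.
    """
    if params is None:
        params = ForceFieldParams.default()
    e = params.electrostatics
    I = (ion.monovalent_mM + e["divalent_strength_weight"] * ion.divalent_mM) * 1e-3
    lb = bjerrum_length(ion.T, params)
    n_per_A3 = 6.02214076e-4 * I  # number density of unit charges, A^-3
    kappa_sq = 8.0 * np.pi * lb * n_per_A3
    return float(1.0 / np.sqrt(kappa_sq))


def effective_charge_fraction(ion: IonCondition, compactness: str = "coil",
                              params: ForceFieldParams | None = None) -> float:
    """Net phosphate charge fraction after counterion condensation.

    Manning condensation leaves a fraction 1/(z*xi) of the bare charge,
    xi = l_B / b with axial spacing b set by the structure state
    (``coil`` or ``helix``).  With divalent ions present, the fraction
    interpolates between the monovalent-only and divalent-dominated limits
    by the divalent binding fraction x = a*sqrt(c2)/(a*sqrt(c2) + c1).
    """
    if params is None:
        params = ForceFieldParams.default()
    e = params.electrostatics
    if compactness not in e["manning_spacing"]:
        raise ValueError(f"unknown compactness state {compactness!r}")
    b = e["manning_spacing"][compactness]
    xi = bjerrum_length(ion.T, params) / b
    f_mono = min(1.0, 1.0 / xi)
    f_di = min(1.0, 1.0 / (2.0 * xi))
    c2 = ion.divalent_mM * 1e-3
    if c2 == 0.0:
        return f_mono
    c1 = ion.monovalent_mM * 1e-3
    a = e["divalent_competition_a"]
    x = a * np.sqrt(c2) / (a * np.sqrt(c2) + c1)
    return float((1.0 - x) * f_mono + x * f_di)


def electrostatic_energy(chain: BeadChain, ion: IonCondition,
                         params: ForceFieldParams | None = None,
                         compactness: str = "coil") -> float:
    """Screened Coulomb repulsion between reduced phosphate charges.

    P-bead pairs closer than 2 backbone bonds are excluded (their geometry
    is governed by the bonded terms).
    """
    if params is None:
        params = ForceFieldParams.default()
    e = params.electrostatics
    ionkey = ("elconst", ion.T, ion.monovalent_mM, ion.divalent_mM, compactness)
    hit = params._pair_cache.get(ionkey)
    if hit is None:
        hit = (effective_charge_fraction(ion, compactness, params)
               * abs(params.phosphate_charge),
               debye_length(ion, params),
               water_dielectric(ion.T))
        if len(params._pair_cache) < 4096:
            params._pair_cache[ionkey] = hit
    Q, lam, eps_r = hit
    from ._kernels import screened_coulomb_kernel

    P = chain.P
    n = len(chain)
    min_sep = int(e["min_backbone_separation"])
    prefactor = e["coulomb_const"] * Q * Q / eps_r
    if screened_coulomb_kernel is not None:
        return float(screened_coulomb_kernel(np.ascontiguousarray(P),
                                             min_sep, prefactor, lam))
    ck = ("el", n)
    hit = params._pair_cache.get(ck)
    if hit is None:
        hit = np.triu_indices(n, k=min_sep)
        params._pair_cache[ck] = hit
    i, j = hit
    if len(i) == 0:
        return 0.0
    diff = P[i] - P[j]
    d = np.sqrt(np.einsum("ij,ij->i", diff, diff))
    return float(prefactor * np.sum(np.exp(-d / lam) / d))


# ---------------------------------------------------------------------------
# total energy
# ---------------------------------------------------------------------------

def total_energy(chain: BeadChain, bpmap: BasePairMap, stems: StemAnnotation,
                 ion: IonCondition, params: ForceFieldParams | None = None,
                 flags: EnergyFlags = EnergyFlags(),
                 helical_mask=None) -> EnergyBreakdown:
    """Full eight-term energy breakdown for a conformation.

    ``helical_mask`` selects the bonded parameter set per residue; by
    default every residue uses the nonhelical (folding-stage) set.
    """
    if params is None:
        params = ForceFieldParams.default()
    n = len(chain)
    if helical_mask is None:
        helical_mask = np.zeros(n, dtype=bool)
    U_b, U_a, U_d = bonded_energy(chain, helical_mask, params)
    U_exc = excluded_volume_energy(chain, params)
    U_bp = pairing_energy(chain, bpmap, params)
    U_bs = stacking_energy(chain, bpmap, ion, params)
    U_cs = coaxial_energy(chain, stems, ion, params, enabled=flags.coaxial)
    U_el = (electrostatic_energy(chain, ion, params)
            if flags.electrostatics else 0.0)
    return EnergyBreakdown(U_b, U_a, U_d, U_exc, U_bp, U_bs, U_cs, U_el)


def evaluate_state(chain: BeadChain, ion: IonCondition,
                   params: ForceFieldParams | None = None,
                   flags: EnergyFlags = EnergyFlags(),
                   bonded_mode: str = "nonhelical",
                   helical_mask=None):
    """Energy, base-pair map and stems for the current coordinates.

    The pair map is detected over the full pairing-well support so that the
    Metropolis energy is a deterministic function of the coordinates.
    ``bonded_mode`` is ``nonhelical`` (folding stage; every residue uses the
    soft bonded set) or ``paired`` (currently paired residues use the
    helical set).  An explicit ``helical_mask`` overrides both -- the
    refinement stage passes the mask frozen from the annealed fold.
    """
    from .cg_model import BasePairMap, candidate_pairs

    if params is None:
        params = ForceFieldParams.default()
    cands = sorted(candidate_pairs(chain, params,
                                   window=params.pairing["cutoff_offset"]))
    taken = set()
    pairs = []
    U_bp = 0.0
    for e, i, j in cands:
        if i in taken or j in taken:
            continue
        pairs.append((i, j))
        taken.update((i, j))
        U_bp += e
    bpmap = BasePairMap.from_pairs(pairs, len(chain))
    stems = annotate_stems(bpmap, len(chain))
    if helical_mask is not None:
        mask = np.asarray(helical_mask, dtype=bool)
    elif bonded_mode == "paired":
        mask = np.zeros(len(chain), dtype=bool)
        for i, j in bpmap.pairs:
            mask[i] = mask[j] = True
    elif bonded_mode == "nonhelical":
        mask = np.zeros(len(chain), dtype=bool)
    else:
        raise ValueError(f"unknown bonded_mode {bonded_mode!r}")
    U_b, U_a, U_d = bonded_energy(chain, mask, params)
    U_exc = excluded_volume_energy(chain, params)
    U_bs = stacking_energy(chain, bpmap, ion, params)
    U_cs = coaxial_energy(chain, stems, ion, params, enabled=flags.coaxial)
    U_el = (electrostatic_energy(chain, ion, params)
            if flags.electrostatics else 0.0)
    breakdown = EnergyBreakdown(U_b, U_a, U_d, U_exc, U_bp, U_bs, U_cs, U_el)
    return breakdown, bpmap, stems
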