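"""Three-bead coarse-grained representation of an RNA chain.

Each nucleotide is reduced to three beads: a phosphate bead (P) at the
phosphorus position, a sugar bead (C) at the C4' atom and a base bead (N)
at the glycosidic nitrogen (N1 for pyrimidines, N9 for purines).  This
module defines the chain container, builds self-avoiding random chains
from sequence, coarse-grains all-atom PDB structures, and provides the
geometric detection of formed base pairs and helical stems.
"""
from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np

BEAD_NAMES = ("P", "C", "N")
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CU")
_COMPLEMENT_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


class ChainGrowthError(RuntimeError):
    """Raised when a self-avoiding chain cannot be grown further."""

    def __init__(self, residue_index: int, attempts: int):
        self.residue_index = residue_index
        super().__init__(
            f"failed to place residue {residue_index} without steric overlap "
            f"after {attempts} attempts"
        )


class CoarseGrainError(ValueError):
    """Raised when an all-atom structure cannot be coarse-grained."""


@dataclass(frozen=True)
class Sequence:
    """An RNA sequence over the AUGC alphabet (T is mapped to U on input)."""

    residues: str
    name: str = "rna"

    def __post_init__(self):
        seq = self.residues.upper().replace("T", "U")
        if len(seq) < 2:
            raise ValueError("sequence must have length >= 2")
        bad = set(seq) - set("AUGC")
        if bad:
            raise ValueError(f"invalid bases in sequence: {sorted(bad)}")
        object.__setattr__(self, "residues", seq)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def __getitem__(self, i):
        return self.residues[i]

    @classmethod
    def from_fasta(cls, path) -> "Sequence":
        """Read a single-record FASTA file."""
        name, lines = None, []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    if name is not None:
                        raise ValueError("FASTA file must contain a single record")
                    name = line[1:].split()[0] or "rna"
                else:
                    lines.append(line)
        if not lines:
            raise ValueError("no sequence found in FASTA file")
        return cls("".join(lines), name=name or "rna")


def is_complementary(a: str, b: str, allow_gu: bool = True) -> bool:
    """Watson-Crick (and optionally GU wobble) complementarity."""
    pair = (a, b)
    return pair in _COMPLEMENT_WC or (allow_gu and pair in _WOBBLE)


def pair_type(a: str, b: str) -> str:
    """Canonical pair class: 'GC', 'AU' or 'GU'."""
    key = "".join(sorted((a, b)))
    types = {"CG": "GC", "AU": "AU", "GU": "GU"}
    if key not in types:
        raise ValueError(f"{a}-{b} is not a canonical pair")
    return types[key]


@dataclass
class BeadChain:
    """A coarse-grained chain: sequence plus (n, 3, 3) bead coordinates.

    ``coords[i, k]`` is the xyz position (Angstrom) of bead ``k`` of residue
    ``i`` with bead order P, C, N.
    """

    sequence: Sequence
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.sequence), 3, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"(n={len(self.sequence)}, 3, 3)"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_beads(self) -> int:
        return 3 * len(self)

    @property
    def P(self) -> np.ndarray:
        return self.coords[:, 0]

    @property
    def C(self) -> np.ndarray:
        return self.coords[:, 1]

    @property
    def N(self) -> np.ndarray:
        return self.coords[:, 2]

    @property
    def flat(self) -> np.ndarray:
        """All bead positions as a (3n, 3) array in residue-major order."""
        return self.coords.reshape(-1, 3)

    def copy(self) -> "BeadChain":
        return BeadChain(self.sequence, self.coords.copy())


@dataclass(frozen=True)
class BasePairMap:
    """A set of formed canonical base pairs, one partner per base."""

    pairs: frozenset  # of (i, j) tuples with i < j
    n: int

    def __post_init__(self):
        seen = {}
        for i, j in self.pairs:
            if not (0 <= i < j < self.n):
                raise ValueError(f"pair ({i}, {j}) out of range for n={self.n}")
            for k in (i, j):
                if k in seen:
                    raise ValueError(f"residue {k} participates in more than one pair")
                seen[k] = True

    @classmethod
    def from_pairs(cls, pairs, n: int) -> "BasePairMap":
        return cls(frozenset((min(i, j), max(i, j)) for i, j in pairs), n)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair) -> bool:
        i, j = pair
        return (min(i, j), max(i, j)) in self.pairs

    def partner(self, i: int):
        for a, b in self.pairs:
            if a == i:
                return b
            if b == i:
                return a
        return None

    def sorted_pairs(self):
        return sorted(self.pairs)


@dataclass(frozen=True)
class Stem:
    """A maximal ladder of base pairs consecutive on both strands."""

    pairs: tuple  # ((i, j), (i+1, j-1), ...)

    @property
    def length(self) -> int:
        return len(self.pairs)

    @property
    def five_prime_start(self) -> int:
        return self.pairs[0][0]

    @property
    def residues(self) -> frozenset:
        return frozenset(k for p in self.pairs for k in p)


@dataclass(frozen=True)
class StemAnnotation:
    """Stems plus loop decomposition of a secondary structure."""

    stems: tuple  # of Stem, ordered by 5'-most paired residue
    loops: tuple  # of (start, end) inclusive runs of unpaired residues
    n: int
    interhelix_loop_length: int | None = None  # nt between the two stems (H-type)

    @property
    def n_stems(self) -> int:
        return len(self.stems)


# ---------------------------------------------------------------------------
# chain construction
# ---------------------------------------------------------------------------

def sequence_to_random_chain(
    seq: Sequence,
    seed: int,
    params=None,
    max_attempts: int = 200,
) -> BeadChain:
    """Grow a self-avoiding random chain from a sequence.

    Only chain connectivity (bonded equilibrium lengths) and excluded volume
    act during growth; the result is the random starting configuration for
    annealing.  Deterministic for a fixed seed.
    """
    from .forcefield import ForceFieldParams

    if params is None:
        params = ForceFieldParams.default()
    rng = np.random.default_rng(seed)
    n = len(seq)
    b_pc = params.bonded["nonhelical"]["bonds"]["PC"][0]
    b_cp = params.bonded["nonhelical"]["bonds"]["CP"][0]
    b_cn = params.bonded["nonhelical"]["bonds"]["CN"][0]
    radii = params.bead_radii_array(seq)  # (3n,)
    tol = params.excluded_volume["overlap_tolerance"]

    placed = np.empty((3 * n, 3))
    count = 0

    def random_dir():
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)

    def try_place(anchor_index, bond, bead_index):
        nonlocal count
        anchor = placed[anchor_index]
        for _ in range(max_attempts):
            pos = anchor + bond * random_dir()
            d = np.linalg.norm(placed[:count] - pos, axis=1)
            min_allowed = radii[:count] + radii[bead_index] - tol
            d[anchor_index] = np.inf  # bonded anchor is exempt
            if np.any(d < min_allowed):
                continue
            placed[count] = pos
            count += 1
            return pos
        raise ChainGrowthError(bead_index // 3, max_attempts)

    placed[0] = 0.0
    count = 1
    coords = np.empty((n, 3, 3))
    coords[0, 0] = placed[0]
    for i in range(n):
        if i > 0:
            # P_i bonded to C_{i-1}, which sits at bead slot 3(i-1)+1
            coords[i, 0] = try_place(3 * (i - 1) + 1, b_cp, 3 * i)
        coords[i, 1] = try_place(3 * i, b_pc, 3 * i + 1)
        coords[i, 2] = try_place(3 * i + 1, b_cn, 3 * i + 2)
    return BeadChain(seq, coords)


# ---------------------------------------------------------------------------
# coarse-graining all-atom structures
# ---------------------------------------------------------------------------

_RNA_RESNAMES = {"A": "A", "U": "U", "G": "G", "C": "C",
                 "RA": "A", "RU": "U", "RG": "G", "RC": "C"}


def coarse_grain_structure(source, chain_id: str | None = None) -> BeadChain:
    """Coarse-grain an all-atom RNA structure (PDB file or biotite AtomArray).

    P beads coincide with phosphorus atoms, C beads with C4' and N beads with
    N1 (pyrimidine) or N9 (purine).  A 5'-terminal residue lacking a
    phosphate gets its P bead extrapolated along the C4'(0)->C4'(1)
    direction so that per-residue bead counts stay uniform.
    """
    import biotite.structure as struc

    atoms = _load_atom_array(source)
    if chain_id is not None:
        atoms = atoms[atoms.chain_id == chain_id]
    if atoms.array_length() == 0:
        raise CoarseGrainError("no atoms found (wrong chain id?)")

    residues = []  # (res_id, base, {atom_name: xyz})
    starts = struc.get_residue_starts(atoms, add_exclusive_stop=True)
    for lo, hi in zip(starts[:-1], starts[1:]):
        res_id = atoms.res_id[lo]
        res_name = atoms.res_name[lo].strip()
        base = _RNA_RESNAMES.get(res_name)
        if base is None:
            warnings.warn(f"skipping non-RNA residue {res_name} {res_id}")
            continue
        lookup = {nm: atoms.coord[lo + k] for k, nm in enumerate(atoms.atom_name[lo:hi])}
        residues.append((int(res_id), base, lookup))

    if len(residues) < 2:
        raise CoarseGrainError("fewer than 2 RNA residues found")

    seq = Sequence("".join(b for _, b, _ in residues), name="pdb")
    coords = np.empty((len(residues), 3, 3))
    for i, (res_id, base, lookup) in enumerate(residues):
        n_name = "N9" if base in PURINES else "N1"
        if "C4'" not in lookup:
            raise CoarseGrainError(f"residue {base}{res_id} is missing atom C4'")
        if n_name not in lookup:
            raise CoarseGrainError(f"residue {base}{res_id} is missing atom {n_name}")
        coords[i, 1] = lookup["C4'"]
        coords[i, 2] = lookup[n_name]
        if "P" in lookup:
            coords[i, 0] = lookup["P"]
        elif i == 0:
            coords[i, 0] = np.nan  # fill after C beads are known
        else:
            raise CoarseGrainError(f"residue {base}{res_id} is missing atom P")
    if np.any(np.isnan(coords[0, 0])):
        direction = coords[0, 1] - coords[1, 1]
        direction /= np.linalg.norm(direction)
        coords[0, 0] = coords[0, 1] + 3.8 * direction
    return BeadChain(seq, coords)


def _load_atom_array(source):
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if isinstance(source, struc.AtomArray):
        return source
    if isinstance(source, struc.AtomArrayStack):
        return source[0]
    if isinstance(source, io.StringIO) or hasattr(source, "read"):
        pdb = PDBFile.read(source)
    else:
        pdb = PDBFile.read(str(source))
    atoms = pdb.get_structure(model=1, altloc="first")
    return atoms


def chain_to_pdb(chain: BeadChain, path=None):
    """Write a CG chain as a PDB file with pseudo-atoms P, C4', N1/N9.

    Standard viewers render the result; `coarse_grain_structure` reads it
    back to the same coordinates (round trip).
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = len(chain)
    atoms = struc.AtomArray(3 * n)
    atoms.coord = chain.flat.astype(np.float32)
    names, res_ids, res_names, elements = [], [], [], []
    for i, base in enumerate(chain.sequence):
        n_name = "N9" if base in PURINES else "N1"
        names.extend(["P", "C4'", n_name])
        res_ids.extend([i + 1] * 3)
        res_names.extend([base] * 3)
        elements.extend(["P", "C", "N"])
    atoms.atom_name = np.array(names)
    atoms.res_id = np.array(res_ids)
    atoms.res_name = np.array(res_names)
    atoms.element = np.array(elements)
    atoms.chain_id = np.full(3 * n, "A")
    atoms.hetero = np.zeros(3 * n, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(atoms)
    if path is not None:
        pdb.write(str(path))
    return pdb


# ---------------------------------------------------------------------------
# base-pair detection and stem annotation
# ---------------------------------------------------------------------------

def backbone_tangents(chain: BeadChain) -> np.ndarray:
    """Normalized local 5'->3' backbone direction at each residue.

    Central difference over the sugar beads (one-sided at the termini);
    used to reject parallel-strand pairing geometries.
    """
    C = chain.C
    n = len(chain)
    lo = np.clip(np.arange(n) - 1, 0, n - 1)
    hi = np.clip(np.arange(n) + 1, 0, n - 1)
    t = C[hi] - C[lo]
    return t / np.sqrt(np.einsum("ij,ij->i", t, t))[:, None]


def antiparallel_factor(tdot, p) -> np.ndarray:
    """Linear ramp 1 -> 0 as the paired strands' tangent dot grows."""
    lo, hi = p["antiparallel_lo"], p["antiparallel_hi"]
    return np.clip((hi - tdot) / (hi - lo), 0.0, 1.0)


def candidate_pairs(
    chain: BeadChain,
    params,
    window: float | None = None,
) -> list:
    """Geometric candidate pairs with their pairing energies.

    Returns a list of ``(energy, i, j)`` for complementary residues whose
    N-N distance lies within ``window`` of the pairing-well minimum and
    whose glycosidic vectors face each other; no conflict resolution.
    """
    p = params.pairing
    if window is None:
        window = p["detect_window"]
    seq = chain.sequence.residues
    ck = ("cand", seq)
    hit = params._pair_cache.get(ck)
    if hit is None:
        min_sep = p["min_loop"] + 1
        ii, jj, depths = [], [], []
        for i in range(len(seq)):
            for j in range(i + min_sep, len(seq)):
                if is_complementary(seq[i], seq[j]):
                    ii.append(i)
                    jj.append(j)
                    depths.append(p["depth"][pair_type(seq[i], seq[j])])
        hit = (np.array(ii, dtype=int), np.array(jj, dtype=int),
               np.array(depths, dtype=float))
        params._pair_cache[ck] = hit
    ii, jj, depths = hit
    if len(ii) == 0:
        return []
    N, C = chain.N, chain.C
    diff = N[ii] - N[jj]
    d = np.sqrt(np.einsum("ij,ij->i", diff, diff))
    dev = d - p["r0"]
    near = np.abs(dev) <= window
    if not np.any(near):
        return []
    u = N - C
    u /= np.sqrt(np.einsum("ij,ij->i", u, u))[:, None]
    facing = -np.einsum("ij,ij->i", u[ii[near]], u[jj[near]]) / p["orientation_ref"]
    g_or = np.clip(facing, 0.0, 1.0)
    t = backbone_tangents(chain)
    tdot = np.einsum("ij,ij->i", t[ii[near]], t[jj[near]])
    g_ap = antiparallel_factor(tdot, p)
    ok = (g_or >= p["orientation_detect_min"]) & (g_ap > 0.0)
    if not np.any(ok):
        return []
    g_d = np.exp(-dev[near][ok] ** 2 / (2.0 * p["sigma"] ** 2))
    energies = -depths[near][ok] * g_d * g_or[ok] * g_ap[ok]
    isel = ii[near][ok]
    jsel = jj[near][ok]
    return [(float(e), int(i), int(j))
            for e, i, j in zip(energies, isel, jsel)]


def detect_base_pairs(
    chain: BeadChain,
    params=None,
    window: float | None = None,
) -> BasePairMap:
    """Detect formed canonical base pairs from coordinates.

    Pairs must be sequence-complementary (WC or GU), within the
    distance/orientation window of the pairing well and at least
    ``min_loop`` nucleotides apart; conflicts (a base with several
    candidate partners) are resolved greedily by best pairing energy.
    """
    from .forcefield import ForceFieldParams

    if params is None:
        params = ForceFieldParams.default()
    cands = sorted(candidate_pairs(chain, params, window))
    taken = set()
    pairs = []
    for energy, i, j in cands:
        if i in taken or j in taken:
            continue
        pairs.append((i, j))
        taken.update((i, j))
    return BasePairMap.from_pairs(pairs, len(chain))


def annotate_stems(bpmap: BasePairMap, n: int | None = None) -> StemAnnotation:
    """Group base pairs into maximal stems and classify loops.

    Stems are maximal runs of pairs consecutive on both strands
    ((i, j), (i+1, j-1), ...).  For two-stem H-type maps the stems are
    labeled Stem 1 / Stem 2 by their 5'-most paired residue and the
    interhelix (junction) loop length is reported.
    """
    if n is None:
        n = bpmap.n
    pairs = bpmap.sorted_pairs()
    stems = []
    current = []
    for p in pairs:
        if current and p == (current[-1][0] + 1, current[-1][1] - 1):
            current.append(p)
        else:
            if current:
                stems.append(Stem(tuple(current)))
            current = [p]
    if current:
        stems.append(Stem(tuple(current)))
    stems.sort(key=lambda s: s.five_prime_start)

    paired = np.zeros(n, dtype=bool)
    for i, j in pairs:
        paired[i] = paired[j] = True
    loops = []
    start = None
    for k in range(n):
        if not paired[k] and start is None:
            start = k
        elif paired[k] and start is not None:
            loops.append((start, k - 1))
            start = None
    if start is not None:
        loops.append((start, n - 1))

    junction = None
    if len(stems) == 2:
        junction = _junction_length(stems[0], stems[1])
    return StemAnnotation(tuple(stems), tuple(loops), n, junction)


def _junction_length(stem_a: Stem, stem_b: Stem) -> int:
    """Smallest number of nucleotides strictly between the two stems."""
    best = None
    for pa in (stem_a.pairs[0], stem_a.pairs[-1]):
        for pb in (stem_b.pairs[0], stem_b.pairs[-1]):
            for x in pa:
                for y in pb:
                    gap = abs(x - y) - 1
                    if best is None or gap < best:
                        best = gap
    return max(best, 0)


def interface_pairs(stem_a: Stem, stem_b: Stem):
    """The two base pairs (one per stem) closest in sequence across the junction."""
    best = None
    for pa in (stem_a.pairs[0], stem_a.pairs[-1]):
        for pb in (stem_b.pairs[0], stem_b.pairs[-1]):
            gap = min(abs(x - y) for x in pa for y in pb) - 1
            if best is None or gap < best[0]:
                best = (gap, pa, pb)
    return best[1], best[2]
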