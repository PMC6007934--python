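"""RMSD evaluation of predicted structures against a reference.

RMSDs are computed over the sugar (C) beads against the reference C4'
positions after optimal least-squares superposition (proper rotation
only, no reflection), with ensemble mean/minimum statistics.
Correspondence is strictly by residue index.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .cg_model import BeadChain


@dataclass
class StructureComparison:
    """Per-member RMSD over C beads plus ensemble statistics (Angstrom)."""

    rmsds: np.ndarray
    mean_rmsd: float
    min_rmsd: float
    best_index: int

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"member": np.arange(len(self.rmsds)),
                             "rmsd_A": self.rmsds})

    def report(self) -> str:
        lines = [f"{i}\t{r:.3f}" for i, r in enumerate(self.rmsds)]
        lines.append(f"# mean RMSD: {self.mean_rmsd:.3f} A")
        lines.append(f"# min RMSD:  {self.min_rmsd:.3f} A "
                     f"(member {self.best_index})")
        return "\n".join(lines)


def superpose_rmsd(mobile: np.ndarray, reference: np.ndarray) -> tuple:
    """Optimal-superposition RMSD between two corresponding point sets.

    Returns ``(rmsd, (rotation, translation))`` where the rigid transform
    maps the mobile set onto the reference.  Reflections are disallowed.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(
            f"point counts differ: mobile {mobile.shape[0]} vs "
            f"reference {reference.shape[0]}")
    if mobile.shape[0] < 3:
        raise ValueError("superposition needs at least 3 points")
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - mu_r, mobile - mu_m)
    diff = rot.apply(mobile - mu_m) - (reference - mu_r)
    rmsd = np.sqrt(np.mean(np.einsum("ij,ij->i", diff, diff)))
    translation = mu_r - rot.apply(mu_m)
    return float(rmsd), (rot, translation)


def ensemble_rmsd(ensemble: list, reference: BeadChain) -> StructureComparison:
    """Mean/minimum RMSD of an ensemble of CG chains over C beads.

    Every member must share the reference's length (no trimming or
    alignment; all comparisons are same-sequence by construction).
    """
    if not ensemble:
        raise ValueError("ensemble is empty")
    ref_C = reference.C
    rmsds = np.empty(len(ensemble))
    for k, member in enumerate(ensemble):
        if len(member) != len(reference):
            raise ValueError(
                f"ensemble member {k} has {len(member)} residues, "
                f"reference has {len(reference)}")
        rmsds[k], _ = superpose_rmsd(member.C, ref_C)
    best = int(np.argmin(rmsds))
    return StructureComparison(rmsds, float(rmsds.mean()),
                               float(rmsds[best]), best)
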