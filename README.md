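# pkfold

Coarse-grained folding, stability and unfolding-pathway prediction for
small RNAs — hairpins and H-type pseudoknots — in monovalent and mixed
monovalent/divalent ion solutions, from sequence alone.

Pseudoknots are minimal RNA tertiary motifs: a hairpin whose loop pairs
with bases outside the loop, giving two stems (Stem 1, Stem 2) that often
stack coaxially.  Their stability and thermal unfolding pathway
(F → S1/S2 → U, through hairpin intermediates that keep one stem) depend
strongly on sequence and on the ion atmosphere, which most structure
predictors ignore.  `pkfold` is for computational/biophysical RNA people
who want a sequence-in, thermodynamics-out model that treats salt
explicitly but cheaply.

## Model in brief

Each nucleotide is three beads — P (phosphate), C (C4' sugar), N
(glycosidic nitrogen N1/N9) — with the energy

```
U = U_b + U_a + U_d + U_exc + U_bp + U_bs + U_cs + U_el
```

bonded terms (dual parameter sets for helical vs single-stranded
regions), excluded volume, base pairing (Gaussian wells with facing and
antiparallel gates), nearest-neighbor base stacking G(T) = ΔH − TΔS,
coaxial stacking of stems across ≤1-nt junctions, and Debye–Hückel
screened phosphate repulsion with Manning counterion condensation and a
K⁺/Mg²⁺ competition term.  Conformations are sampled by pivot-move
Metropolis Monte Carlo; folding uses simulated annealing; melting curves
come from per-temperature trajectories classified into F/S1/S2/U and
fitted to two-state logistics

```
f_F(T) = 1/(1 + e^{(T−Tm1)/dT1}),   f_U(T) = 1 − 1/(1 + e^{(T−Tm2)/dT2})
f(T)   = 1 − [(1−f_I) f_F(T) + f_I (1 − f_U(T))]
```

giving the two melting temperatures (F→I and I→U), the denatured-pair
fraction f(T) and its derivative df/dT.  See `docs/methods.md` for the
full description and every default.

## Worked example

```python
import numpy as np
import pkfold as pk
from pkfold.synthetic import PSEUDOKNOT_17NT, ideal_pseudoknot_chain, pseudoknot_reference

params = pk.ForceFieldParams.default()
ion = pk.IonCondition.from_celsius(25.0, 100.0)   # 100 mM K+
result = pk.melting_scan(
    PSEUDOKNOT_17NT, ion, np.linspace(15, 125, 9), params,
    steps_per_T=12000, record_interval=100, seed=7,
    reference_stems=pseudoknot_reference()[1],
    initial_chain=ideal_pseudoknot_chain(params))
print(result.fractions.to_dataframe().round(2).to_string(index=False))
print({k: round(v, 2) for k, v in result.summary().items()})
```

prints the per-temperature state fractions

```
   T_C  f_F  f_S1  f_S2  f_U
 15.00 0.99  0.01  0.00 0.00
 28.75 0.97  0.01  0.02 0.00
 42.50 1.00  0.00  0.00 0.00
 56.25 0.93  0.04  0.02 0.00
 70.00 0.38  0.59  0.01 0.01
 83.75 0.00  0.59  0.00 0.41
 97.50 0.00  0.21  0.00 0.79
111.25 0.00  0.00  0.00 1.00
125.00 0.00  0.00  0.00 1.00
{'Tm1_C': 67.97, 'dT1_C': 4.17, 'Tm2_C': 87.21, 'dT2_C': 6.58, 'f_I': 0.32}
```

Read: the 17-nt toy pseudoknot is fully folded (F) below ~56 °C; around
70–97 °C the AU-rich Stem 2 has melted while the GC-rich Stem 1 persists
(the S1 hairpin intermediate dominates — the unfolding pathway is
F → S1 → U); above ~110 °C the chain is coil (U).  Tm1 ≈ 68 °C is the
midpoint of the F→I transition, Tm2 ≈ 87 °C of I→U, and f_I ≈ 0.3 is the
fraction of base pairs already lost at the intermediate's population
maximum.  Individual reduced-sampling scans scatter by a few degrees;
averaging three replicates per condition (as `scripts/acceptance.py`
does) moves Tm1 from ~64 °C at 10 mM K⁺ to ~75 °C at 1 M K⁺: salt
stabilizes the compact pseudoknot, and Tm1 responds more strongly than
Tm2, because forming the pseudoknot from the hairpin intermediate
involves the larger charge buildup.

Shell equivalents (`fold`, `melt`, `rmsd`, `fixtures`):

```bash
pkfold fold --sequence GGGAAAUCCC --monovalent 1000 --outdir run/
pkfold melt --sequence GGGAAAUCCC --monovalent 100 --divalent 1.0 --outdir melt/
```

The `examples/` scripts each demonstrate one capability (folding a
hairpin, a melting scan, RMSD evaluation, the salt model) and print a
short interpretation with their numbers.

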