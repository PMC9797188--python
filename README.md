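# ppiscreen

Virtual screening of protein–protein interactions (PPIs) from
predicted-structure confidence.

Deep-learning structure predictors can fold two proteins "simultaneously" as
a putative dimer; whether the resulting interface is believable is encoded in
the predicted aligned error (PAE) matrix. `ppiscreen` turns that signal into
a screening pipeline for structural biologists: score predicted complexes,
reject steric nonsense, and rank a whole library of candidate partners — for
example every protein of the *E. coli* cell envelope — against a query
protein, all without touching the GPU inference step, which sits behind a
pluggable adapter.

## The score

Interface residues are residues with a heavy atom strictly within 4.5 Å of
another chain. With N_I interface residues, PAE entries e_ij, and the
TM-score normalisation d0(n) = 1.24·(max(n,19) − 15)^⅓ − 1.8,

    iScore = max_{i∈I} mean_{j∈I, chain(j)≠chain(i)} 1 / (1 + (e_ij / d0(N_I))²)

Only cross-chain frames contribute, so the score measures predicted
inter-chain geometry, not monomer fold quality. It lives in [0, 1]; 0.4, 0.5
and 0.7 mark medium, high and very-high confidence tiers. Models whose
interface is mostly atomic overlap (clash indicator ≥ 0.4: fraction of
interface residues with an inter-chain atom pair under 1.6 Å) are rejected
before ranking, and each screening target is represented by the highest
surviving iScore across a 10-network × 2-seed prediction sweep.

See `docs/methods.md` for the full model description, parameter rationale and
limitations.

## Worked example

Generate a toy dimer (two facing poly-alanine helices) with a confident
interface (cross-chain PAE 1 Å), then score it:

```sh
$ ppiscreen fixtures dimer --out demo --pae-interface 1.0
wrote dimer.pdb and dimer_conf.json to demo

$ ppiscreen score demo/dimer.pdb demo/dimer_conf.json
model	iscore	tier	clash	mean_plddt	n_interface
dimer_s7_o0	0.48	medium	0.00	80	26
```

The 26-residue interface with uniform 1 Å cross-chain error scores
iScore 0.48 — medium confidence (the toy interface is small, so d0(26) ≈ 0.96
makes even 1 Å of error costly) — with no clashing interface residues
(clash 0.00) and a flat pLDDT of 80. The same numbers are reachable from
Python:

```python
from ppiscreen import FixtureSpec, bind, find_interface, score_model
from ppiscreen.fixtures import make_dimer, make_confidence

spec = FixtureSpec(pae_interface=1.0)
model = make_dimer(spec)
card = score_model(bind(model, make_confidence(model, spec)))
print(card.iscore, card.tier, card.n_interface)  # 0.48... medium 26
```

Inter-chain contacts, sorted by chain-A residue then distance:

```sh
$ ppiscreen contacts demo/dimer.pdb --chains A B | head -4
chain_a	resnum_a	resname_a	chain_b	resnum_b	resname_b	min_distance_A
A	1	ALA	B	1	ALA	2.400
A	1	ALA	B	4	ALA	4.252
A	4	ALA	B	5	ALA	3.099
```

A full mock screen — synthetic proteome table, library filtering (primary
location not cytosolic, non-standard sequences removed, mature chains only),
pair jobs under the 1600-residue cap, 20 predictions per target via the
deterministic mock adapter, ranking, histogram and hit table:

```sh
ppiscreen fixtures proteome --n 30 --out proteome.tsv
ppiscreen envelopome build proteome.tsv --out lib
ppiscreen screen --query SYN00029 --library proteome.tsv --out run
```

Real predictor backends plug in by implementing the adapter contract
`(features, model_name, seed, max_recycles) -> (StructureModel,
ConfidenceBundle)` and passing it to `ppiscreen.screening.run_screen`.

## Layout

- `src/ppiscreen/model_io.py` — mmCIF/PDB + confidence JSON I/O, the
  structure/confidence binding contract
- `src/ppiscreen/interface.py` — interface detection, contact maps, clash
  indicator
- `src/ppiscreen/scoring.py` — d0, iScore, pTM, pLDDT means, tiers,
  best-model selection
- `src/ppiscreen/features.py` — monomer feature crop/cap, MSA pairing,
  complex assembly
- `src/ppiscreen/envelopome.py` — screening-library construction from
  proteome annotations
- `src/ppiscreen/screening.py` — resumable query-vs-library orchestration
  and reporting
- `src/ppiscreen/fixtures.py` — synthetic structures, confidence bundles,
  proteomes, mock predictor
- `src/ppiscreen/validate.py` — recompute scores from deposited model files
- `src/ppiscreen/cli.py` — the `ppiscreen` command
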