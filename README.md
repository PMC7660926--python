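# stabscan

Saturation stability scanning of protein domains: per-variant folding
stability changes (ΔΔG, kcal/mol scale) for **all possible missense
substitutions and single-residue in-frame deletions**, plus downstream
integration with allele-frequency and clinical-label tables into fishtail
and heatmap classification outputs.

## What it does

- **Structure I/O** (`stabscan.structure_io`): fixed-column PDB read/write
  with author residue numbering, altloc resolution, slicing to a domain,
  and flagging (not dropping) residues with unresolved backbones.
- **Variants** (`stabscan.variants`): parsing/formatting of short variant
  labels (`R362C`, `ΔK508`/`delK508`/`K508del`) and saturation enumeration
  (20 substitution identities + 1 deletion per resolved position).
- **Scoring** (`stabscan.energy`): a pluggable scoring contract with
  (a) a deterministic, coarse-grained builtin scorer (steric clash, burial
  mismatch via Cβ contact counts, backbone strain, side-chain volume
  mismatch) usable at desk scale, and (b) an adapter for an external
  all-atom relax/score tool (configured command template; raises a
  declared-unavailable error when no binary is configured — never a silent
  fallback). `relax` is a seeded jitter + greedy-descent minimisation that
  never returns a score above the input's.
- **Deletion modeling** (`stabscan.deletion_modeling`): ensembles of
  re-closed backbone models per deletion. The backbone gap is closed by a
  symmetric tapered blend over a window of residues on each side, each
  model gets an independent seeded jitter, and all models are geometry
  validated (consecutive Cα–Cα within 2.8–4.3 Å). Terminal deletions trim
  without closure and are flagged.
- **ΔΔG protocols** (`stabscan.ddg`): missense ΔΔG = mean of 3 variant
  scoring iterations minus mean of 3 wild-type iterations, divided by 2.9
  to a kcal/mol scale. Deletion ΔΔG = median of 25 models × 2 relax
  trajectories (50 scores), minus the 10th percentile of the per-position
  ΔG distribution, divided by 2.9. All constants live in `ProtocolConfig`
  (the defaults reproduce the published protocol exactly) and are recorded
  in every output record. Sign convention: **positive ΔΔG = destabilizing**
  (ΔΔG = E_variant − E_wild-type).
- **Annotation** (`stabscan.annotate`): joins ΔΔG records with gnomAD-style
  frequency and ClinVar-style label tables (outer on the ΔΔG side; absence
  from gnomAD is censoring, not frequency 0), three-way stability
  classification (neutral < 1.0 ≤ intermediate < 3.0 ≤ destabilized,
  kcal/mol), per-segment heatmap matrices (deletion row first), and
  consensus-motif scanning (`[PA]xxS`-style patterns, overlaps included).
- **Synthetic data** (`stabscan.synthetic`): ideal α-helices built from
  textbook backbone geometry (φ = −57°, ψ = −47°), a packed antiparallel
  two-helix bundle with geometric buried/exposed/linker ground truth, and
  annotation tables with a planted fishtail structure for recovery tests.

> **Note on absolute values.** The builtin scorer is a coarse-grained,
> artifact-defined stand-in that makes the *protocol* testable at desk
> scale. It is **not** expected to reproduce published per-variant ΔΔG
> values; those benchmarks require the external all-atom backend and the
> crystallographic domain structure (see `tests/test_acceptance.py`,
> criterion 3).

## CLI

```sh
# synthetic inputs
stabscan synth helix --n 21 --out-dir out/helix
stabscan synth bundle --out-dir out/bundle           # + ground-truth JSON
stabscan synth tables --n-common 50 --n-rare-pathogenic 20 --out-dir out/tables

# full saturation scan (all substitutions + all deletions)
stabscan scan --structure out/helix/helix.pdb --chain A --seed 1 --out-dir out/scan

# deletion-only scan
stabscan deletion-scan --structure out/helix/helix.pdb --chain A --out-dir out/dels

# join with annotation tables; classify stability
stabscan annotate --ddg out/scan/results.tsv \
    --freq out/tables/frequency.tsv --labels out/tables/labels.tsv \
    --out-dir out/fishtail

# per-segment heatmap (TSV + PNG)
stabscan heatmap --ddg out/scan/results.tsv --start 1 --end 21 --out-dir out/hm

# consensus-motif scan
stabscan motif-scan --sequence GGPAASGGKVKVLFKGG --out-dir out/motifs
```

Every run writes `manifest.json` before computing and embeds its hash in
each output header; re-running with the same seed reproduces outputs
byte-identically on the builtin backend. Protocol flags default to the
published constants (`--n-models 25 --n-traj 2 --n-iter-missense 3
--baseline-percentile 10 --kcal-divisor 2.9`).

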