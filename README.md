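# methcore

Epiallele and methylation-core analysis of targeted bisulfite amplicon
sequencing.

## The problem

Deep bisulfite sequencing of a promoter amplicon reads out, for every single
DNA molecule, the binary methylation state of each CpG it covers. Each
distinct binary pattern is an **epiallele**. Molecule populations from real
tissue are heterogeneous: individual epialleles are almost never frequent
enough to be statistically meaningful on their own. Yet a *subset* of CpGs —
possibly non-contiguous — can be jointly methylated in a substantial,
stable fraction of molecules. Such a **methylation core** marks a family of
epialleles descended from a common ancestral molecule: the core CpGs are
under selection while the flanking CpGs fluctuate freely. Core composition
and frequency change along differentiation time courses and differ between
cell types, making cores compact fingerprints of cell identity.

`methcore` is a reusable pipeline for this analysis, aimed at groups doing
targeted bisulfite (amplicon) sequencing of a handful of loci at depth:

1. **QC** — align each merged read to the bisulfite-converted amplicon
   reference (C/T-ambiguous at CpGs) and apply four retention filters:
   length ≥ 50% of the reference, primer identity ≥ 80%, bisulfite
   conversion efficiency ≥ 98% (on non-CpG cytosines), aligned fraction
   ≥ 60%. Per-filter attrition is reported and always sums to the input.
2. **Epialleles** — call M/U per CpG per read (reads with any ambiguous
   CpG call are dropped) and tabulate pattern counts; a k-CpG amplicon has
   a 2^k pattern space (64 for the 6-CpG designs).
3. **Population statistics** — per-CpG and overall average methylation,
   Shannon entropy H = −Σ pᵢ log₂ pᵢ of the epiallele distribution (bits),
   unpaired t tests between groups, Pearson correlation between stage-wise
   epiallele distributions, PCA of epiallele abundance across samples.
4. **Core discovery** — for every CpG subset S (size 2..6), compare the
   observed joint methylation frequency f_obs(S) against the CpG-wise
   independence expectation f_exp(S) = Π_{j∈S} m_j/n using the upper tail
   of the joint count under the null. A core is significant when
   p < 10⁻¹⁰, f_obs > f_exp and f_obs ≥ 0.25 of molecules. Nested cores
   with near-equal prevalence are collapsed to the largest (maximal core).
5. **Trajectories** — cores are tracked across ordered time points
   (T0/T2/T4/T8/T14-style designs), linking composition changes such as
   105-138-150 → 105-138 into one lineage and reporting the joint
   frequency of each label set at every time.
6. **Identity tree** — samples are summarized by the union of their
   maximal-core labels, compared by Jaccard distance, and clustered by
   UPGMA into an ultrametric newick tree that groups samples sharing core
   composition.

A synthetic-data module generates seeded bisulfite amplicon populations —
epiallele families with planted cores, imperfect bisulfite conversion
(default 98.5%), sequencing errors and ambiguous CpG calls — so the whole
pipeline can be exercised and validated without any sequencing data.

## Worked example

Simulate a five-time-point DDO-like experiment in which a core at CpGs
105-138-150 (TSS-relative labels) transiently expands — family prevalence
0.3 → 0.4 → 0.7 → 0.4 → 0.3 — then run the full read-level pipeline:

```python
from methcore import *

ref = make_reference("DDO", seed=9)                       # 6 CpGs, labels 105..343
tsc = ddo_timecourse(seed=1, n_reads=800, reference=ref)  # transient schedule
manifest, truth = simulate_timecourse(tsc, "demo_sim")

tables, cores_by_time = {}, {}
for entry, t in zip(manifest, tsc.time_labels):
    retained, report = run_qc(load_reads(entry.read_file), ref)
    calls = [call_methylation(a, ref) for _, a in retained]
    matrix, n_amb = build_matrix(calls, ref.cpg_labels, entry.sample_id)
    report.record_ambiguous_drops(n_amb)
    tables[t] = tabulate(matrix)
    cores_by_time[t] = maximal_cores(enumerate_cores(tables[t]))
    print(f"{t}: {report.n_retained}/{report.n_input} reads retained, "
          f"entropy {shannon_entropy(tables[t]):.2f} bits, "
          f"top core {cores_by_time[t][0].label_str if cores_by_time[t] else '-'}")

trajs = track_cores(cores_by_time, tables, tsc.time_labels)
tr = next(t for t in trajs if t.cpg_labels == (105, 138, 150))
print("105-138-150 frequency:",
      " ".join(f"{t}={f:.3f}" for t, f in zip(tr.time_labels, tr.frequencies)))
print("stable:", tr.stable)
```

Output:

```
T0: 514/800 reads retained, entropy 3.43 bits, top core 105-138-150
T2: 498/800 reads retained, entropy 3.44 bits, top core 105-138-150
T4: 499/800 reads retained, entropy 3.12 bits, top core 105-138-150
T8: 518/800 reads retained, entropy 3.36 bits, top core 105-138-150
T14: 521/800 reads retained, entropy 3.28 bits, top core 105-138-150
105-138-150 frequency: T0=0.272 T2=0.349 T4=0.601 T8=0.361 T14=0.255
stable: True
```

About a third of the simulated reads are removed by the strict per-read
conversion filter (a 98% per-read cutoff under a 98.5% per-base rate), as
expected. The planted core is the top maximal core at every time; its
recovered frequency traces the planted transient, peaking at T4 where
population entropy correspondingly dips (the population is most
homogeneous at the methylation peak). The core is significant at
consecutive time points, so the trajectory is flagged stable.

The same run is available from the shell:

```sh
methcore simulate --preset ddo --n-reads 800 --seed 1 --out-dir demo_sim
methcore run-all --config run.yaml     # manifest, references, thresholds
```

which writes `qc/`, `epialleles/`, `stats/`, `cores/`, `trajectories/` and
`tree/` under the configured output directory.

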