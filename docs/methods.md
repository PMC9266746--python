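# Methods

## The assay being modelled

A ribonuclease's dinucleotide preference is read out by digesting a short
single-stranded RNA probe that contains every ordered dinucleotide NpN
(4² = 16) and homopolymer runs of each base, then identifying and
semi-quantifying the oligonucleotide digestion products by LC-MS/MS.
Because every endonucleolytic product is delimited by two cuts (or a
molecule terminus), the set of observed products determines which bonds
were cleaved, and their abundances determine how efficiently. The packaged
reference probe is the 31-mer `GCAUCAGAAAUACACCCGUAGGGCUUUGAGA` (16/16
dinucleotides; maximal runs AAA at 8, CCC at 15, GGG at 21, UUU at 25).
Coordinates are 1-based everywhere; bond `i` joins residues `i` and `i+1`.

## Chemistry and masses

Residues are stored as elemental formulas of the internal chain unit
(nucleoside monophosphate − H₂O) in a user-extensible TSV; numeric masses
are computed at load time from one atomic-mass table (pyteomics), so no
mass is ever transcribed by hand. A chain with 5′-OH/3′-OH termini has
composition `Σ residues + H2O − HPO3`; terminal phosphates add `HPO3`, and
the 2′,3′-cyclic phosphate left by transesterifying RNases is one water
lighter than the linear 3′-phosphate (18.0106 Da). Products are matched
tolerant of ± one water so cyclic and post-hydrolysis linear termini pool
by default. Modification codes are bracketed short names (`m5C`, `m7G`,
`m1A`, `m22G`, `D`, ...), each mapping to exactly one parent base for
dinucleotide classification.

Fragment ladders follow standard nucleic-acid nomenclature (5′ series
a/b/c/d, 3′ series w/x/y/z, defaults c/y/w/a−B — the dominant RNA CID
channels). All series reduce to subsequence compositions plus fixed
offsets, so complementary pairs obey `c_i + y_(n−i) = M + H2O` exactly.
Negative-mode ions are deprotonated: `m/z = (M − |z|·m_H⁺)/|z|`. The ppm
tolerance (default 10) and charge range (−1..−6) of peak matching are
configuration, not claims about any instrument.

## The independent-cut digestion model

Each bond of each molecule is cut independently with probability `p(N5,
N3)` given by the flanking dinucleotide; exact-residue-code overrides take
precedence over parent-base entries, which encodes modified-nucleotide
behaviour (dihydrouridine cleaved like U; 5′ m1A or m7G blocking cleavage).
Directionality conventions ("cleaves 5′ of U", "cleaves 3′ of C") are both
expressed on the ordered (5′ base, 3′ base) pair. A product spanning
`i..j` occurs with probability

    P(i,j) = cut(i−1) · cut(j) · Π_{i≤k<j} (1 − cut(k)),   cut(0)=cut(n)=1.

Expected abundances under this model conserve residue mass exactly
(`Σ length·count = n·parent_length`), which the tests verify against
exhaustive enumeration of all 2^(n−1) cut patterns for short parents.
Product enumeration for reporting is bounded by `max_missed` (default 2)
and `min_probability` (default 1e-4) so low-probability models stay finite;
expectation computation is exhaustive. Whether real missed cleavages
reflect per-molecule independence or processivity is not resolved by
endpoint data; the independent-cut model is the declared, testable choice,
and the digest is treated as a single endpoint snapshot (no kinetics).

## The efficiency estimator

For bond `i`: `x = ½(Σ abundance ending at i + Σ abundance starting at
i+1)`, `y = Σ abundance spanning i`, `efficiency = 100·x/(x+y)`. The
two-end average is a deliberate design choice: each cut produces exactly
one product on either side, so averaging avoids double counting, makes the
estimator *exactly* unbiased under the independent-cut model (on noiseless
expectations it returns 100·p at every covered bond, verified to 1e-9
against the cut-pattern oracle), and halves the bias when one side is
undetectable. Molecule termini are not cut evidence. `x+y = 0` is
reported as no-coverage (NaN), strictly distinct from a measured 0%.

Category boundaries: `<5` extremely low, `[5,25)` low, `[25,50]` moderate,
`>50` efficient — boundary values at 5 and 25 belong to the higher band's
printed lower edge, and exactly 50 is moderate. The statistic is scale
invariant, so only relative abundances matter (the method is
semi-quantitative; no ionization-efficiency correction is attempted).

Unanchored products are placed at every exact-code occurrence in the
parent; `split` mode divides abundance equally among placements,
`unique_only` excludes ambiguous products from scoring. Bonds aggregate
per exact-code dinucleotide (`[m5C]pU` separate from `CpU`); per-class
summaries report mean, sd and min–max pooled over bonds × replicates plus
the across-bond range of per-bond means, since the two ranges answer
different questions and neither is privileged.

## Synthetic data

`simulate_digest` generates identification tables from a ground-truth
model: expected counts × independent lognormal(0, σ) multiplicative noise
per product per replicate, with products shorter than
`min_detectable_length` (default 2 nt) removed — mononucleotides escape
LC-MS detection. Defaults are the assay's study conditions: 4 replicates,
σ = 0.2, 10⁴ molecules (the scale is immaterial to the ratio statistic).
The simulator writes ground truth alongside its outputs and is
byte-deterministic per seed. It does not model per-oligonucleotide
ionization response, retention, isotope envelopes or spectral noise, so
passing recovery tests demonstrate estimator correctness under the stated
noise model — not robustness to every instrumental artefact.

Two bias phenomena are deliberate features, not bugs, and are covered by
tests:

- at a run like UUU with an undetectable single-U product, the cut-evidence
  term loses one of its two ends and the recovered efficiency sits below
  100·p (the worked example recovers ~34 for p = 0.5);
- a bond flanked by two mononucleotide products on both sides (the middle
  GpG of the 31-mer under a complete G-specific digest) has no detectable
  evidence at all and is reported as no-coverage.

## Numerical and recovery properties

- Estimator exactness: noiseless, full-detection recovery is exact to
  1e-9 over random parents ≤ 8 nt and probability grids {0, .25, .5, .75, 1}.
- Stochastic recovery: at σ = 0.2, 4 replicates, 10⁴ molecules, per-bond
  efficiency means land within 5 points of 100·p across seeds (measured
  worst case ≈ 4.9). At σ = 0.3 the same 5-point envelope is *not*
  reliable (worst case ≈ 7 points over 10 seeds): averaging per-replicate
  ratios carries Jensen-type noise amplification for bonds whose x or y is
  dominated by one or two products. This is a known limitation of the
  mean-of-ratios aggregation, stated here rather than hidden by a looser
  test bound.
- Efficiencies are clamped to ≤ 100 to absorb float round-off when y = 0.
- Ties in peak matching break by smallest |ppm|, then larger charge
  magnitude; sequence isomers are isobaric and always reported together as
  ambiguous.

## Open choices made

- The probe's 5′ terminus chemistry is taken as 5′-OH (synthetic RNA as
  purchased); configurable on every parse/read call.
- "Homopolymer run" means ≥ 3 identical bases; length-2 repeats are
  already counted as their XpX dinucleotide.
- The probe designer (de Bruijn linearization + greedy run extension) makes
  no length-minimality claim beyond the 17-nt information floor.
- The bundled cleavage presets (`t1`, `mc1`, `cusativin`) encode published
  per-dinucleotide efficiency ranges as range-midpoint probabilities with
  modified-residue overrides; they are convenient starting points, not
  re-measurements.
- Simulated tables carry the true start anchor by default (the simulator
  knows it); placement of unanchored products is exercised separately so
  the recovery tests measure estimator error, not placement ambiguity.
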