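# Methods

## Problem and model

`exconsv` locates protein regions that are conserved in one paralog family
but not in its sister families. The motivating system is the largest
subunits of the three plant DNA-dependent RNA polymerases: NRPB1 (Pol II),
NRPD1 (Pol IV) and NRPE1 (Pol V). Pol IV and Pol V arose from Pol II by
gene duplication, so positions conserved across *all* three families mark
shared polymerase function, while positions conserved *exclusively* in
NRPD1 are candidates for Pol IV-specific activities (e.g. partner-protein
docking sites such as the CYC-YPxF clamp-head motif).

The statistic is computed per reference residue i (positions are numbered
on one designated reference sequence, mapped through the master alignment):

    EC(i) = g_focal(i) − max over paralog groups g_other(i)

where g(i) is a per-group conservation grade on the 1–9 scale (9 = most
conserved, ConSurf convention). EC therefore lies in [−8, 8]; a sustained
stretch of high EC is an exclusively conserved region.

## Dataset QC

Candidate subunits must be strictly longer than 900 aa (`min_length`,
literal reading of "over 900") and contain the invariant catalytic metal-A
motif `DFDGD` as an exact substring. Terminal `*` stop characters are
stripped *before* the length check. Both criteria are parameters of
`qc_filter`.

## Motif scanners and classification

Patterns use a PROSITE-like dialect (`C-Y-x(0,1)-C`). Matching semantics
are fixed for determinism: scan left to right, at each anchor take the
longest match, resume past it (non-overlapping, leftmost-first).

* **Heptads (Pol II CTD).** Consensus `Y-S-P-[TS]-S-P-S`, at most 2
  mismatches per heptad, at least 5 tandem copies, searched in the
  C-terminal window (last 40% of the sequence; the literature says "in the
  CTD" without a boundary, so the window fraction is a parameter). Score =
  run length.
* **GW/WG (Pol V CTD AGO hooks).** Greedy left-to-right count of
  non-overlapping `GW`/`WG` dimers in the C-terminal window (`GWG` counts
  once); "repeated" means ≥ 5 by default.
* **CYC-YPxF (Pol IV clamp head).** Bipartite: the CYC sub-motif
  `C-Y-x(0,1)-C` followed within ≤ 20 residues by `Y-P-x-F`. The optional
  wildcard inside the CYC sub-motif accommodates both the 3-residue (CYC)
  and the 4-residue (CYxC, cysteines four apart) readings, which the
  source material does not disambiguate; both pattern strings and the
  spacer bound are configuration fields, not constants. A CYC match with
  no qualifying YPxF is reported as the shortened CYC-YP *partial* motif
  typical of bryophyte NRPE1-like subunits.

Classification applies an ordered rule table (first rule fires): heptads →
B1_like; full CYC-YPxF → D1_like; repeated GW/WG without any CYC evidence
→ E1_like; partial CYC-YP with repeated GW/WG, or partial CYC-YP in a
bryophyte-flagged record → DE_like; otherwise unclassified. The bryophyte
flag comes from a `clade=bryophyte` header tag or a DE_like group hint.

## Conservation score

Phylogeny-aware rate estimation (ConSurf/Rate4Site) is replaced by a
deterministic, dependency-free column score in the style of Capra & Singh:

    raw(i) = JSD'(p_column, background) × (non-gap fraction)

`p_column` is the residue frequency distribution of the column restricted
to one group's rows (gaps and X excluded); `background` defaults to the
Robinson–Robinson database frequencies (`--background uniform` is
available); JSD' is the Jensen–Shannon divergence in bits, bounded in
[0, 1]. Columns dominated by a single residue diverge strongly from the
background and score high; columns that resemble a background draw score
near zero; under a uniform background a perfectly uniform column scores
exactly 0. The non-gap factor makes a half-gapped invariant column score
exactly half its gap-free counterpart. Note the score is residue-aware:
an invariant tryptophan column (rare residue) outscores an invariant
alanine column.

Raw scores are rank-binned within each group into nine equal-frequency
grades (ties share the grade of their mean rank), which makes grades
comparable across groups of different sizes — the property the EC
subtraction needs. Positions with fewer than `min_coverage = 4`
informative residues are UNDEFINED; positions inside the CTD mask (the
repetitive, alignment-unreliable C-terminal domains) are MASKED. Both are
excluded from binning and force EC = 0 downstream: they cannot seed or
extend a region, but a region may be bridged across them.

This substitution — a frequency-based score for an evolutionary-rate
estimate — is the main reason boundary-exact reproduction of region
coordinates from any particular published analysis is not promised; the
EC logic only needs a per-group, per-position conservation *ranking*.

## Region calling

On the EC track:

1. smooth with a centered moving average, window k = 9 (`shrink` edge
   policy by default, so terminal residues stay scoreable; `drop` zeroes
   positions where the full window does not fit);
2. **seed**: positions with smoothed EC ≥ 2 (read as "two grade-ninths
   more conserved than the better paralog");
3. **grow**: each maximal run of consecutive *positive* smoothed values is
   a candidate;
4. **bridge**: candidates separated by strictly fewer than 9 non-positive
   positions merge, transitively, with the gap included in the span
   (`--no-bridge` disables this step);
5. **filter**: merged candidates containing no seed are dropped; survivors
   are labeled EC1, EC2, … by ascending start.

Region endpoints always carry positive smoothed EC, and every seed lies in
exactly one region. Raising the seed threshold can only remove regions.

## Synthetic data

The simulator generates the structure the analysis assumes, with no
download: K groups (default B1/D1/E1, 12 tips each) descend from one root
sequence (drawn from the Robinson–Robinson background) via a star
phylogeny — root → group ancestor (0.6 expected substitutions/site) →
tips (0.3 substitutions/site). Per-site substitution counts are Poisson
(branch length × site multiplier); a substitution replaces the residue by
a background draw excluding the current residue. The default benchmark
plants two 30-aa regions ((301, 330) and (801, 830) of a 1500-aa protein)
whose rate multiplier is 0.02 in D1 and 1.0 elsewhere. A second factory
additionally plants frozen diagnostic motifs (heptads in the B1 CTD, a
GW/WG-rich segment in the E1 CTD, CYC-YPxF at position 115 of D1).

Deliberate simplifications: no indels (sequences are born aligned; a
gap-column injector exists only to exercise the alignment reader and the
coordinate map), no amino-acid exchangeability matrix, no nested tree
within groups, no rate autocorrelation along the sequence. Passing the
recovery benchmark therefore shows the statistic and caller recover a
rate-suppression signal under idealized alignment and star-phylogeny
conditions; it does not show robustness to alignment error, long-branch
effects or indel-rich families.

Recovery scoring: a planted region is recalled when a called region
overlaps it with interval Jaccard ≥ 0.5; precision is the fraction of
called regions matching any planted region at that bound (reported as 1
with a flag when nothing is called); mean Jaccard averages each planted
region's best overlap.

## Numerical choices and degenerate inputs

* Coordinates are 1-based inclusive everywhere (residues and columns);
  BED export converts explicitly to 0-based half-open.
* Grade binning: grade = ceil(9 × mean-rank / n), clipped to [1, 9].
* All-gap columns are UNDEFINED rather than scored; empty patterns,
  ragged alignments, all-gap reference rows, even smoothing windows and
  overlapping mask or planted intervals are hard errors.
* All randomness flows through a single integer seed
  (`numpy.random.default_rng`); identical seeds give byte-identical
  simulator output and pipeline TSVs.

## Benchmark sizes and observed behavior

The shipped benchmarks (test suite and `scripts/acceptance.py`) use 20
simulation replicates for the recovery tier and 50 for the null tier at
the default 1500 aa × 36 sequences, plus 200/500/200 randomized trials for
the moving-average, region-caller and pattern-scanner oracle checks —
sizes chosen so the whole suite completes in well under a minute while
keeping Monte-Carlo error small. Under these conditions the pipeline
recovers every planted region (recall 1.0) with precision ≈ 0.9 and mean
Jaccard ≈ 0.84. The null simulation (no planted contrast) calls ≈ 0.7–1.0
spurious regions per 1500-aa track: with equal-frequency grades the null
EC per position has mean ≈ −1.5 and sd ≈ 3.3, so the k = 9 average crosses
the seed threshold (≈ 3 sd above the mean) about once per track-length.
Spurious calls are a known, quantified property of the grade-scale
statistic at these settings; raising `seed_threshold` suppresses them at
the cost of shorter called spans.

## Known limitations

* The conservation score ignores phylogeny inside a group; dense clades
  of near-identical sequences inflate apparent conservation.
* Equal-frequency binning forces 1/9 of positions into grade 9 even in a
  uniformly variable group.
* Classification is motif-based, not tree-based; a subunit lacking all
  diagnostic motifs is honestly `unclassified`.
* The CTD mask must be supplied by the user (the repetitive CTDs do not
  align reliably); no automatic CTD boundary detection is attempted.
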