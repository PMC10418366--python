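# Methods

## Problem setting

Classical fixed-charge MD cannot change protonation states during a run, so
the effect of pH on an enzyme is emulated by preparing separate systems
with discrete charge assignments and comparing replicate trajectories
between conditions.  The scientific readout implemented here is
conformational: whether a side chain — above all a catalytic histidine of a
papain-family cysteine protease — occupies a different χ1 rotamer at acidic
pH than at neutral pH, and how often it leaves the catalytically competent
("native") rotameric state.

## Charge schemes

Three named schemes assign integer charges by residue type:

| scheme    | Asp | Glu | His        | Lys | Arg | everything else |
|-----------|-----|-----|------------|-----|-----|-----------------|
| `pH7`     | −1  | −1  | 0          | +1  | +1  | 0               |
| `pH2_all` | 0   | 0   | +1         | +1  | +1  | 0               |
| `pH2_his` | −1  | −1  | +1 at the target His only | +1 | +1 | 0 |

`pH2_his` is a virtual condition isolating the effect of protonating the
catalytic histidine alone.  Termini and cysteines (including the catalytic
thiol, which remains protonated and neutral) contribute zero in every
scheme; with that convention the mature-chain composition of 14 Asp,
10 Glu, 2 His, 4 Lys and 5 Arg yields net charges −15, +11 and −14 — the
integer totals such MD setups report.  How termini were treated in the
original setups is not documented; the all-zero convention is the unique
choice that reproduces all printed totals and is fixed here.  No pKa
prediction or fractional (Henderson–Hasselbalch) charge is attempted:
discreteness is the point of the scheme.

Charges are computed over the mature chain only, using precursor numbering
(positions labelled `i + offset`, default offset 115 for a removed
signal-plus-propeptide segment), so the catalytic triad carries its
customary labels 138/275/295.

The packaged FASTA (`data/tccathl1_mature_synthetic.fasta`) is a
**synthetic stand-in**, not the natural cathepsin L sequence: it was
constructed to match the mature chain's ionizable composition exactly and
to place C138/H275/N295 (plus V277 and A251) at their precursor-numbered
positions.  Every charge-scheme result above is invariant to the identity
of the non-ionizable filler residues, which is why a stand-in suffices for
a fully offline package; users analysing the real enzyme should point the
tools at the genuine UniProt-derived mature chain.

## Circular stacking

χ1 wells frequently straddle the ±180° seam of the dihedral convention.
All angles are therefore duplicated at *a* and *a* + 360° and one
contiguous 360° window is selected — operationally: angles are reduced
mod 360, the widest empty circular gap between sorted values is found, and
the window is cut at that gap's midpoint (ties to the lowest-angle gap; the
representative start in (−180°, 180°] is used so data already clear of the
seam keeps its values).  This guarantees the dominant mode is never split.
Stacking is a frame-by-frame bijection preserving congruence classes
mod 360 and is idempotent.

When two series are compared, the window is chosen from their **pooled**
angles so both histograms share identical bin edges; per-series windows
could manufacture spurious non-overlap at the cut.

## The S_NO statistic

For unit-area histograms *p*, *q* on shared edges with equal bin widths Δ:

    S_NO = Σ|pᵢ − qᵢ| / Σ(pᵢ + qᵢ) = 1 − Σ min(pᵢ, qᵢ)·Δ

the second form being one minus the overlap coefficient.  S_NO is symmetric,
lies in [0, 1], is 0 for identical and 1 for disjoint distributions.  For
equal-length trajectories the raw-count and unit-area formulations
coincide; unit-area is fixed here so replicates of different lengths remain
comparable.

Defaults: histogram (not kernel) densities with **5° bins** (72 per
window).  The binning resolves a σ ≈ 9° well with several bins while
keeping ~100 counts per occupied bin for a 1000-frame replicate; for smooth
von Mises-like data at n ≥ 10⁴, halving the bin width moves S_NO by less
than 0.05 (tested).

**Pairing and selection.**  Replicates of the two conditions are compared
in `matched` pairs by replicate index — appropriate when replicate *k* of
both conditions starts from the same structural model — with `all_pairs`
(Cartesian product) as an option.  A residue is selected as pH-responsive
when S_NO exceeds the threshold (default 0.5, strict inequality) in at
least `min_pairs` (default 2) of `n_pairs` (default 3) pairs.  Replicate
aggregation reports the arithmetic mean ± sample (ddof = 1) standard
deviation of the matched-pair values.  No p-values or multiple-testing
correction: the rule is a fixed reproducibility threshold, not a test.

## Rotamer states and violation events

Frames are classified by circular containment (|angle − center| mod 360 ≤
halfwidth) into disjoint windows; anything else is `other`.  Defaults place
the native in-site window at 190° ± 45° and the out-of-site window at
285° ± 45° — generous margins around the observed well spreads (±9° and
±12°) since classification boundaries, unlike well centers, are an analysis
choice and are config-exposed.

A **violation event** is a maximal run of non-native frames whose duration
is at least `min_dwell` (default 1 ns), where a run's duration is the sum
of per-frame durations (forward time differences, the last frame inheriting
the previous step).  The dwell filter separates sustained excursions from
single-frame noise; event counts are monotone non-increasing in
`min_dwell`.  Because the underlying studies mark such events visually
rather than by a stated dwell rule, synthetic-data tests assert only the
qualitative ordering (destabilized > stabilized variant), never a specific
event count.

## Synthetic trajectory generator

Each rotamer well is a von Mises emission with concentration
κ = 1/σ_rad², the standard circular analog of a Gaussian well of the stated
spread; hidden states follow a per-frame Markov chain.  Defaults emulate
the study design the analysis expects: 1000 frames at 0.1 ns (a 100-ns
trajectory), three replicates per condition, a stable well at
190° ± 9° for the neutral-pH-like condition and, for responsive residues
at the acidic-pH-like condition, a second well at 285° ± 12° with
switching probabilities p(in→out) = 0.05 and p(out→in) = 0.02 per frame.

Those rates give a stationary out-of-site occupancy of 5/7 ≈ 0.71 and mean
dwell times of 2 ns in-site / 5 ns out-of-site.  The rate choice follows
from two constraints: the expected S_NO of a two-well regime against a
stable-well condition approximately equals the realized out-of-site
occupancy, so an out-dominant chain is required for matched-pair S_NO to
exceed the 0.5 selection threshold reliably (as the destabilized catalytic
histidine does, with reported values up to ≈0.9); and dwell times of a few
ns produce several ≥1 ns violation events per 100-ns replicate.  No kinetic
rates are available to fit, so these defaults are chosen for testability,
not physical fidelity.

Per-trajectory seeds are derived deterministically from a base seed via
`numpy.random.SeedSequence` spawn keys, so datasets are bit-reproducible
and replicates are statistically independent.  The hidden state path is
always retained, enabling oracle tests (classification vs generator truth,
occupancy vs the closed-form stationary distribution, transition counts vs
binomial moments).

**What a green synthetic test does not establish.**  The generator emulates
marginal χ1 statistics only: no force-field physics, no solvent, no
correlated multi-residue motion, no autocorrelation structure beyond the
two-state chain, and no RMSD/RMSF behavior.  Agreement on synthetic data
validates the *pipeline arithmetic*, not any claim about a real enzyme's
trajectories, which require the original MD data.

## Numerical choices and degenerate inputs

- Angles are stored in degrees end to end; radians appear only inside math
  kernels.
- S_NO is clipped to [0, 1] against pure float round-off; ties at the
  selection threshold are excluded (strict `>`).
- Empty series, non-increasing time grids, non-stochastic transition
  matrices, overlapping rotamer windows, mismatched bin edges and
  wild-type-mismatched mutations all raise typed errors early.
- Readers accept any strictly increasing time grid (uniform or not); frame
  durations are taken from the grid itself.
- TSV artifacts are written at 4 significant digits for inspection; the
  JSON report keeps full precision.  The report's provenance block records
  the config hash, seed and package version, and the selected-residue list
  is exactly the selection rule applied to the reported S_NO table.

## Known limitations

- No binary trajectory parsing and no dihedral computation from
  coordinates; the pipeline consumes extracted angle series.
- Histogram densities only; a kernel/smoothed S_NO variant is out of scope.
- The charge model ignores termini and non-standard protonation
  microstates by construction.
- The packaged sequence fixture is synthetic (see above); results that
  depend on residue identity outside the ionizable set are not meaningful
  for it.
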