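# Methods

## The habitat and its event stream

The habitat is four housing compartments (1–4) joined in a ring by four
tubes, each tube carrying one antenna at either end. A crossing from
compartment *c* to adjacent compartment *d* produces an origin-side read at
the moment the animal leaves *c* and a destination-side read when it enters
*d*; the gap between the two reads is tube transit. Event logs are CSV
(`time_s,antenna,tag`) with session-relative times in decimal seconds; the
wall-clock session start and dark-phase onset live in metadata because the
analysis needs only relative time and phase alignment. Reading a log
validates it: unknown tags or antennas are collected into a report (never
silently dropped), timestamp disorder up to 0.1 s is re-sorted as benign
logger jitter while larger disorder is rejected as corruption, and repeat
reads of the same tag at the same antenna within 0.5 s (hardware re-reads
of a stationary animal) are merged keeping the first. The debounce window
is configurable and should be set to 0 for simulator-generated streams,
which contain no stationary re-reads but can contain genuine fast
revisits.

## Visit reconstruction

Each read places its animal at a known tube end, hence in a known
compartment. Reconstruction is a deterministic sweep over an animal's
placements:

- consecutive placements in the same compartment extend one visit — in
  particular an origin-side read followed by more reads in the same
  compartment is an aborted exit and does not split the visit;
- a compartment change via both antennas of one tube is a clean crossing:
  the visit ends at the origin-side read, the next starts at the
  destination-side read, and the transit gap belongs to no compartment;
- a change between adjacent compartments *not* witnessed by both reads of
  the connecting tube means a dropped read: the unique connecting tube is
  inserted, the observed endpoint (if either read survived) is kept, and
  the unobserved endpoint is placed at the midpoint of the ambiguous gap;
- a jump between non-adjacent compartments has two equal-length ring paths,
  so no unique repair exists: the visit is truncated at the last consistent
  read and the gap left unassigned.

Every repair is logged with its time and kind. The first visit starts at
the session start (the animal is somewhere before its first read; the first
read's compartment is the best evidence); the last open visit is closed at
the session end. All intervals are half-open `[start, end)` so a boundary
instant is never double-counted. At perfect detection the reconstruction
reproduces the simulator's ground truth interval-for-interval, which the
test suite asserts as an exact (float-equality) check.

## Activity, time budgets, protocol windows

The 84-h protocol is 24 h adaptation followed by 48 h of sociability
testing, analyzed in 12-h bins (7 activity bins; 4 testing bins spanning
hours 24–72). Activity is the number of visits an animal starts in a bin;
the visit ongoing at t = 0 is not a completed transition and is not
counted, which makes activity exactly equal to the simulator's transition
counts. Time budgets divide clipped dwell time by window length, so
t₁+t₂+t₃+t₄ ≤ 1 with the deficit equal to the transit (plus repair-gap)
fraction; transit is deliberately assigned to no compartment, the
conservative reading of per-cage dwell normalization. Bin edges sit at
protocol hours 0, 12, 24, …; the dark-phase onset is labeling metadata and
does not move bin edges.

## In-cohort sociability

For a pair (a, b) and window, per-compartment co-dwelling t_ab_c is the
total length of the pairwise intersections of the two animals' visit
intervals in compartment c, clipped to the window and normalized by window
length — computed by a sorted two-pointer interval sweep, never by
discretization. The statistic is

    S = t_ab − (t_a1·t_b1 + t_a2·t_b2 + t_a3·t_b3 + t_a4·t_b4),
    t_ab = Σ_c t_ab_c ,

time together minus the expectation under independent exploration. Bounds
asserted on every record: t_ab ≤ Σ_c min(t_ac, t_bc) and S ≤ t_ab; S is
symmetric in the pair, which is emitted once in canonical id order. Pair
values entering cohort histograms and tests are the per-pair means over
the four testing bins; per-bin values are emitted alongside so either
pooling convention can be reproduced. Transit counts as "not together"
(consistent with the budget convention — co-dwelling is defined per cage).

## Cohort statistics

**Kolmogorov–Smirnov.** D is the exact supremum gap between the two
empirical CDFs, evaluated at every jump point of the pooled sample (so
ties are handled by evaluating after all jumps at a value). The two-sided
p-value uses the asymptotic Kolmogorov distribution at √(nm/(n+m))·D —
the plain asymptotic form, without small-sample continuity corrections;
tests cross-check D against brute-force enumeration and p against exact
enumeration at sizes where the asymptotics are accurate. Cohort pair
counts (tens of values per cohort) sit in the regime where the asymptotic
p is adequate for the purpose of flagging distributional separation.

**Histograms.** Relative frequencies are counts/n over half-open bins
(last bin closed); they sum to 1 by construction.

**Two-way ANOVA with Fisher's LSD.** Near-cup dwell is analyzed with
stimulus (social vs. non-social) as a within-animal factor — every animal
contributes both values — and genotype as a between-animal factor. The
sums of squares split exactly into a between-animals stratum (genotype,
tested against animals-within-genotype) and a within-animals stratum
(stimulus and genotype×stimulus, tested against the stimulus×animal
residual); the identity SS_total = Σ SS holds exactly, balanced or not
(unbalanced genotype groups use observation-weighted marginal means).
LSD contrasts are uncorrected: within-genotype stimulus differences use
the paired within-stratum residual (SE = √(2·MS_resid/n_g)); between-
genotype differences at one stimulus level use the mean of the two error
mean squares with pooled degrees of freedom, the standard mixed-design
cell-comparison error. Stars (*, **, *** at 0.05, 0.01, 0.001) are a
reporting convention only.

## Three-chamber analysis

The arena is 820 × 420 mm: 300-mm side chambers, a 200-mm center, 10-mm
partitions with 80-mm door openings centered on the short axis. Cups are
100 × 100 mm squares centered in the side chambers; the near-cup zone is
the concentric 140 × 140 mm square (2-cm border). Coordinates originate at
the lower-left corner, x along the long axis, millimeters. For zone
assignment the partition walls are split at their midline between the
neighboring chambers so the three chambers exactly partition the interior;
a sample exactly on a near-cup edge belongs to the near-cup zone (the more
specific zone wins ties), and near-cup dwell is also counted toward its
containing chamber. Each sample contributes its inter-sample interval to
the zone containing its point (the last sample runs to the session end);
untracked (NaN) samples accumulate as missing time, so chamber times plus
missing time reconstruct the session duration exactly. Path length is the
sum of Euclidean steps between consecutive valid samples, with gaps across
missing samples excluded. An animal is excluded iff, in the all-chambers
habituation session or the test session, it spent zero time in at least
one side chamber (no minimum-dwell threshold — any positive dwell counts
as a visit); missing sessions also exclude, with the reason logged.

## The habitat simulator

An agent-based continuous-time Markov model on the ring. Each animal in
compartment *c* waits an exponential time with rate λ(phase) — defaults
λ_dark = 12/h, λ_light = 4/h, alternating every 12 h from the dark onset,
chosen to give nocturnal activity of realistic order (roughly 140 vs. 50
visits per animal per 12-h bin) at desk-scale event volumes (~14k reads
per 10-animal, 84-h run). On firing it moves to one of the two adjacent
compartments, drawn with weight exp(α·m_d) where m_d is the summed
affinity of animals currently in d (default: every pair affiliated with
weight 1; an optional symmetric per-pair matrix enables subgroup
structure). m_d is evaluated at the decision instant; transiting animals
count toward no compartment. The move takes τ = 2 s and emits the two
antenna reads, each kept with probability p_det (default 0.98; hardware
detection is good but imperfect). Initial compartments are uniform, making
each animal's marginal occupancy exactly ¼ at all times under α = 0 — this
is what makes the analytic expectation of S zero and the null calibration
meaningful. Waiting clocks are re-drawn at each phase boundary with the
new rate, statistically exact for exponential clocks. A single seeded RNG
stream advanced in documented order (events in time order, ties by animal
id; per move: origin-detection draw then destination draw; per arrival:
destination-detection draw then next waiting time) makes runs
bit-reproducible; detection draws are consumed whether or not the read is
kept, so runs differing only in p_det share identical dynamics — useful
for dropped-read studies against a common ground truth.

**Affinity response is non-monotone at strong coupling.** Mean S rises
steeply on the weak-coupling branch (≈0 at α=0 through ≈0.15 at α≈0.75
for 10 animals) but falls back beyond it (≈0.10 at α=2): strong affinity
herds the cohort, each animal's budget concentrates on the herd
compartment, and the independence expectation Σ_c t_ac·t_bc rises toward
t_ab — perpetual co-housing in one compartment being exactly the S = 0
null case. This is a property of the statistic, not a simulator artifact:
S measures co-dwelling *beyond* what individual occupancy profiles
explain, and a fully herded cohort has no such excess. Effect-recovery
tests therefore assert strict monotonicity on the weak-coupling branch
(α ∈ {0, 0.25, 0.5, 0.75}); distributional separation between strong
coupling and the null remains enormous (KS D ≈ 0.8–0.9).

What the simulator does not emulate: within-compartment position, sex- or
genotype-dependent movement, habituation drift over days, bout structure
of real locomotion, and antenna false positives (only misses). Passing
end-to-end tests therefore validates the analysis machinery — event
handling, reconstruction, the statistic's null and response — not any
claim about the behavior of real mice.

## The three-chamber walker

A discrete-time biased random walk at 25 samples/s (configurable;
exactness fixtures in the tests use 32 Hz so every inter-sample interval
is binary-representable and conservation checks are exact). Per step:
Gaussian displacement (SD 15 mm default; fixtures use 25 mm for faster
mixing) plus a drift of (3 mm × weight) toward the highest-weight zone's
center; reflecting outer walls; partition crossings allowed only through
the door opening, otherwise the x-displacement is cancelled (the walker
slides along the wall). A `confine` option restricts the walk to one
chamber for doors-closed sessions and forced-non-explorer fixtures. An
attraction weight of 1 on the social cup yields ≈145 s near-cup dwell per
10-min session with full arena coverage — the realistic social-preference
regime; weights ≳2 pin the walker and can trigger the exclusion rule,
which the tests exploit deliberately. The generator emits the true zone
schedule (zone of each emitted sample) alongside the trajectory.

## Numerical conventions and edge cases

- All dwell computations are exact interval arithmetic; the 1-s
  discretized timeline sweep exists only as an independent oracle, with
  agreement bounded by 2·(#interval boundaries)·(1 s)/window.
- Half-open windows everywhere; a visit straddling a window edge is
  clipped, and a boundary instant belongs to the later bin.
- Zero-length windows, empty samples, empty cells, broken ring topologies,
  events before session start, and samples outside the arena (beyond a
  5-mm tracker tolerance) raise errors rather than degrade silently.
- Simultaneous simulator events are ordered by animal id; reconstruction
  is pure (identical inputs → identical outputs, no RNG).
- Sociability records assert their own bounds at construction, so window
  mismatches between budgets and co-dwell fail loudly.

## Problem sizes

Default test and reproduction runs use 10-animal cohorts over the full
84-h protocol (≈7k transitions, ≈14k reads per run), 20 seeds for null
calibration and 5 per affinity level for the effect sweep; three-chamber
runs use 10-min sessions at 25–32 Hz (15–19k samples). These sizes give
Monte-Carlo error comfortably below the effects being checked (null SE of
mean S ≈ 7×10⁻⁴ per 20-seed batch) while keeping the whole suite fast on
a single CPU.

## Known limitations

- Repair rules are heuristics; at detection probabilities well below ~0.9
  the midpoint-split bias becomes visible in time budgets. The repair log
  is the audit trail.
- The asymptotic KS p-value is anti-conservative for very small cohorts
  (< ~10 values per sample); compare with an exact enumeration if pair
  counts are tiny.
- The ANOVA covers exactly the two-factor repeated-measures design used
  for the preference analysis; it is not a general mixed-model engine.
- The walker's door constraint checks endpoint chambers per step; at step
  sizes ≫ door width a fast diagonal step could in principle cut a corner.
  At the default step scale this is negligible.
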