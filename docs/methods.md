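# Methods

## Angles and conventions

All angles are degrees in the half-open interval (−180°, +180°], the
boundary assigned to +180° so a trans peptide reads ω ≈ +180 rather than
−180. Torsions are IUPAC-IUB signed (clockwise positive looking from atom
2 to atom 3), computed with the atan2 form
`atan2(((b1×b2)×(b2×b3))·b̂2, (b1×b2)·(b2×b3))`, which is
numerically stable at 0°/180°. Degenerate geometry (collinear or
coincident atoms) raises rather than returning NaN: a silent NaN entering
a circular mean would corrupt every bin it touches.

Definitions:

- ω = CA_i–C_i–N_{i+1}–CA_{i+1}; ω₃ = O_i–C_i–N_{i+1}–CA_{i+1}.
- Δω = wrap(ω − 180°) for trans bonds, wrap(ω) for cis.
- θ_C = wrap(ω − ω₃ + 180°): carbonyl-carbon pyramidalization, 0 when the
  carbonyl carbon is planar.
- θ_N = wrap(ω_H − ω + 180°) with ω_H = CA_i–C_i–N_{i+1}–H_{i+1}. The
  nitrogen-side construction mirrors θ_C; it is a convention of this
  package (there is no community-standard formula), and it is undefined
  (None, not an exception) without an amide hydrogen — the normal case in
  X-ray models.
- cis/trans: trans iff |wrap(ω − 180°)| ≤ 90°, the 90° tie going to
  trans. Only near-planar bonds survive the survey filters, so the tie
  rule never decides a surviving record.

Circular means are resultant-vector means; the resultant length is
reported as a dispersion diagnostic, and a (near-)zero resultant marks
the mean undefined instead of returning an arbitrary direction.

## Structure reading policies

Parsing is delegated to gemmi behind a small model (chains → residues →
atoms with coordinates, B, occupancy, altloc). Policies, chosen once:

- model 1 only for multi-model files (NMR ensembles are outside an X-ray
  survey's scope);
- altlocs resolved to the highest-occupancy conformer, ties to the
  earlier letter; a residue is flagged partial-occupancy whenever any
  main-chain atom has occupancy < 1;
- "main chain" = {N, CA, C, O} — the crystallographic norm; hydrogens are
  read when deposited, never constructed;
- header resolution and R-factor are captured from REMARK 2/3 or
  `_refine`/`_reflns` and drive an optional entry gate (defaults 1.6 Å,
  R < 0.20); entries lacking a header value pass that check, since a
  pre-culled chain list normally applied it at selection time.

## Survey

One record per residue, always emitted; exclusion is an annotation
(`exclusion_reasons`), never a dropped row, so included + excluded =
total and every exclusion is auditable. Filters: Gly/Pro (unique backbone
chemistry), partial occupancy, cis bonds, termini, chain breaks
(C_i···N_{i+1} > 1.8 Å — geometric, numbering-independent; bonded is
~1.33 Å), and the B-factor rule: a residue is excluded when its mean
main-chain B exceeds 1.3× the mean main-chain B of the entire protein,
all chains pooled (the only well-defined reading for multi-chain
entries). The comparison is strict (27 > 26 excludes at a protein mean of
20 and ratio 1.3).

The bond between residues i and i+1 is attributed to residue i's (φ, ψ):
ψ_i shares the N_{i+1} atom with that bond, which is what makes the
ψ-dependence of Δω and θ_C well defined.

Binning uses 15°×15° cells centred on multiples of 15° (so survey cells
and a computational (φ,ψ) grid coincide node-for-node), half-open on both
axes to make assignment total and unique. Cells below the per-cell count
threshold (default 100, the database-scale rule for trusting a bin mean)
are kept but flagged and excluded from profiles; desk-scale runs lower
the threshold explicitly (the analysis scripts use 20 and say so).

## Trend fits

The harmonic fit is ordinary least squares on {sin(3ψ), cos(3ψ), 1} with
the period fixed at 120° — extrema every 60° imply k = 3; the period is
never searched. Amplitude = √(a²+b²); the phase is defined by the
invariant y(ψ) = A·sin(3(ψ − phase)) + offset (hence phase =
atan2(−b, a)/3, normalized to [0°, 120°)). Zero crossings are the roots
of the full fitted model including the offset: |offset| > amplitude means
no crossings; offset = 0 gives six roots exactly 60° apart.

Both fits treat angular deviations as reals. This is valid because
surveyed Δω and θ_C live within a few degrees of zero (validity bound
|y| < 90°); no circular regression is attempted. The θ_C-on-Δω regression
runs on per-record values by default with a per-bin-means mode, since
either could reasonably feed a summary statistic.

## Backbone model

NeRF placement: atom d is positioned from anchors (a, b, c) by bond
length, bond angle and torsion; the three defining constraints are
satisfied to ~1e-9 and are the test oracle (plus an independently coded
rotation-based placement). A chain is stored as the anchor coordinates of
the first N, CA, C plus per-residue internal coordinates; build and
extract are exact inverses including global position, verified to 1e-6 on
randomized chains.

Synthesis uses Engh–Huber-style covalent geometry (N–CA 1.458 Å, CA–C
1.525 Å, C–N 1.329 Å, C=O 1.231 Å, standard valence angles) held in one
overridable table. The carbonyl O is placed by the ω₃ torsion about C–N,
which makes θ_C directly controllable: the generator sets
Δω = A·sin(3(ψ − phase)) + N(0, σ_ω), θ_C = slope·Δω + intercept +
N(0, σ_θ), then ω = 180 + Δω and ω₃ = ω + 180 − θ_C.

Defaults are the study conditions: A = 2.0°, phase 0°, σ_ω = 1.0°,
slope 0.6, σ_θ = 0.5°, 25 chains × 82 residues = 2000 interior bonds —
an amplitude and noise scale typical of what high-resolution surveys
report for Δω, at a sample size where the amplitude standard error
(≈ σ_ω·√(2/n) ≈ 0.03°) makes recovery within ±0.1° a fair test. The
(φ,ψ) sampler is a three-basin Gaussian mixture (α −63/−43 ±10°, w 0.35;
β −120/135 ±20/25°, w 0.45; PPII −70/150 ±12°, w 0.20) — enough ψ spread
to condition the k = 3 harmonic basis while keeping a protein-like
Ramachandran footprint. A `("fixed", φ, ψ)` sampler supports exact
single-condition checks.

What the generator does **not** emulate: real covalent-geometry
variation, side chains, coordinate error correlated with B-factors,
sequence effects, or any φ-dependence of Δω. Passing the recovery tests
therefore shows the pipeline is correct and unbiased on its own model
family — not that real proteins follow that model.

ω-idealization extracts internal coordinates, sets every **trans** ω to
exactly 180° (cis bonds untouched — the experiment concerns trans
planarity), preserves everything else, and rebuilds from the same anchor.
Because the anchor frame is shared, unsuperposed per-residue Cα
displacement is well defined; the report also carries the mean and max
displacement and the Kabsch RMSD (scipy `align_vectors`, proper rotation
guaranteed), since "trace difference" admits several readings. Distortion
grows monotonically with a single bond's |Δω| and is idempotent under
re-idealization; at 121 residues and ω noise of sd 6.8° the Kabsch RMSD
lands at several ångströms (≈ 5 Å for the seed in `analysis/04`), the
chain-scale consequence of per-bond deviations.

θ_N is not generated by default (synthetic chains carry no hydrogens); an
option adds amide H exactly in plane, giving θ_N ≡ 0 as a scaffold for
testing the θ_N code path only.

## Numerical choices and limitations

- Tolerances: torsion identities 1e-9°; build/extract round trips 1e-6
  (° and Å) — double precision leaves ~1e-8 of trig/accumulation noise
  over a chain, so 1e-6 is tight but honest.
- Problem sizes: 2000 records for trend recovery, 100 randomized chains
  for the inverse-pair sweep, 121 residues for the distortion experiment
  — sizes at which every check completes in seconds.
- The harmonic fit is linear in its basis, so rank deficiency (all ψ
  equal) and short inputs (n < 4) raise typed errors; a constant
  regressor in the linear fit raises, a constant response returns r = 0
  with a flag.
- Survey counts depend on deposition conventions (altloc usage, partial
  occupancies); the audit trail makes any alternative counting rule
  recoverable from the same records.
- Per-record and per-bin regressions differ slightly by construction
  (binning weights conformers differently); both are exposed.
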