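# Methods

## Scope and model

The package converts three kinds of input — proteomics abundances
(iBAQ), imaging enrichments, and organelle geometry — into a molecular
census of membraneless organelles, and from the census into mean
intermolecular distances that are compared against the Debye length,
the range of screened electrostatic interactions. The underlying
assumptions are:

- molecules are randomly (Poisson) distributed within an organelle;
  pronounced internal substructure would change the distances;
- each molecule pervades a sphere of diameter twice its radius of
  gyration, the region it can reach to form contacts;
- fluorescence intensity is proportional to concentration in the
  regime relevant for nuclear proteins (sub-tens-of-µM), so the
  background-subtracted intensity ratio equals the concentration
  ratio α.

## Census

**Calibration.** N = a·iBAQ is fit by least squares through the origin
(a = Σxy/Σx²) because the relation has a single scale parameter and no
intercept; the reported standard error is the textbook through-origin
value √(Σr²/(n−1)/Σx²). iBAQ units are arbitrary linear units. A zero
or missing iBAQ marks an undetected protein, which receives the
detection-limit copy number (default 407, a fixed configurable
constant; it is not rescaled with the calibration slope).

**Partition.** For an organelle class with n_org copies of volume
V_org in a nucleus of volume V_nuc,
N_org = α·N_tot·V_org/((α−1)·n_org·V_org + V_nuc). The α→∞ limit
(exclusive localization) is evaluated analytically as N_tot/n_org.
Conservation (n_org·N_org + c_np·V_np = N_tot) holds algebraically and
is enforced to 1e-9 relative in tests.

**RNA.** The nuclear ribonucleotide count is
M_tot·f_nuc/MW·N_A — the molar formula multiplied by Avogadro's number
so that downstream bookkeeping is in molecule counts. The organelle sum
in the nucleoplasm concentration includes organelle multiplicity
(Σ α_i·n_i·V_i), consistent with the structure of the protein
partition. Ribonucleotides are converted to molecules by the
organelle's typical RNA length (14,000 nt for nucleolar precursor
rRNA, 2790 nt median mRNA elsewhere); molecule counts may be
fractional internally and are rounded only in reports.

**Nucleosomes.** The whole-cell budget is half the theoretical H4
count (two H4 per nucleosome). Organelles flagged as satellite-rich
(`dapi_bias_correction`) have their DAPI enrichment divided by 1.5
before partitioning, compensating DAPI's preference for AT-rich
repeats; the flag defaults to off and is set per organelle in the
configuration, since the correction is established only for
heterochromatin-focus-like bodies. The nucleosome molecular weight
defaults to the histone octamer (108 kDa) plus one repeat length of
dsDNA at 650 g/mol/bp (≈229 kDa at 186 bp); it is a configurable
bookkeeping value, not a measured one.

## Conformations

Per-residue order/disorder flags are segmented into domains by a
centered 5-residue majority window; ties and truncated edge windows
resolve to ordered, and runs shorter than the window are absorbed into
their flanks (the window length is the only externally fixed choice;
the tie-break and absorption rule are this package's, chosen to make
segmentation idempotent). Disordered-domain radii of gyration come
from a power law R_g = 0.254·N^0.522 nm and the denatured-chain
reference from R_g = 0.19·N^0.588 nm; both laws are explicit
`ScalingLaw` parameters and substitutable, as coefficient choices for
such laws vary across the literature.

The expanded diameter Σ R_g + √(Σ R_g²) is capped at the denatured
chain evaluated on the protein's total residue count, and additionally
floored at the (AlphaFold-floored) relaxed diameter: without that
floor, a compact protein whose predicted diameter exceeds its
denatured-chain diameter would order its conformations inconsistently.
With it, predicted ≤ relaxed ≤ expanded holds for every decomposition.
Preassembled complexes (Mediator, RNA polymerase II elongation
complexes) are species without domain decompositions; their diameters
are direct inputs and identical across conformations unless the user
supplies per-conformation species variants.

## Distances

The nearest-neighbor statistic uses the *unnormalized* upper
incomplete gamma function Γ(1/3, 8φ); the convention is pinned by the
dilute limit, which must reproduce the Poisson mean
Γ(4/3)·(4πn/3)^{−1/3} (verified to 0.1% at φ = 10⁻⁶ and by Monte-Carlo
oracles in the tests). The analytic expression is always evaluated
first and the random-close-packing clamp (Δ_surface = 0 for φ ≥ 0.65)
applied afterwards, so the clamp is the only discontinuity. Mixtures
use the count-weighted third-moment radius with φ computed from r_avg
and the total count — the effective one-component substitution — not a
per-species φ sum; the two differ only at third-moment level. r is
d_conformation/2 uniformly, where d is the floored/capped conformation
diameter. A scenario whose classes hold no molecules returns a zero-φ
state with infinite distances and a warning rather than an error, so
sweeps over scenarios stay total.

## Scoring and rendering

S_D is continuous at λ_D (both branches equal 1 there) and
non-increasing. The acceptance boundary is inclusive: a score of
exactly 0.5 passes, and one passing scenario of the three suffices for
a PSCP/LLPS-compatible call — three low scores are what favor ICBS.
Scores are computed from relaxed-conformation distances by default,
the intermediate of the three size models.

Virtual microscopy draws one confocal-pixel volume: per-species counts
are Poisson-sampled at the organelle concentration (a voxel is a
random sample of the organelle, so fixed expected counts would
misrepresent small-number organelles), placed uniformly in a 250 nm
sphere with hard-sphere rejection (bounded attempt budget, then
overlap is allowed), and projected orthographically far-to-near.
Output bytes are deterministic for a fixed seed.

## Synthetic cells and oracles

The generator emulates the study conditions the census is designed
for: a 450 µm³ diploid nucleus (mESC scale) hosting a nucleolar-GC-like
class (2 × 30 µm³, RNA enrichment 5, nucleosome depletion 0.3, 14 kt
RNA) and a heterochromatin-focus-like class (10 × 5 µm³, RNA
enrichment 0.5, DAPI enrichment 3 with satellite-bias correction);
true copies log-uniform on 10³–10⁷ (the proteome-wide range); iBAQ =
copies/a with mean-one lognormal noise (σ = 0.2 in the noisy setting,
i.e. 20% multiplicative error); enrichments log-uniform on 0.2–20 with
10% exclusively localized species; six calibration anchors, matching
the number of experimentally counted reference proteins; 1–4 domains
per protein with compact-globule ordered R_g (0.22·N^0.38 nm) and
law-derived disordered R_g. What the generator does *not* emulate:
correlated replicate structure in mass spectrometry, intensity
quantification error in α, inhomogeneous molecule distributions inside
organelles, and real per-protein domain architectures — so passing
recovery tests demonstrate the estimator algebra and calibration
statistics, not robustness to those real-data effects.

The Poisson oracle samples points in a periodic cube (edge bias would
otherwise depress the mean) and the hard-sphere oracle uses random
sequential insertion, restricted to φ ≤ 0.3, safely below the
insertion jamming density (~0.38). Oracle problem sizes — 10⁵ points
for the dilute check (sampling error ≪ the 2% band) and 2000 spheres
at φ = 0.1 — keep each check within seconds while leaving Monte-Carlo
error far below the acceptance bands.

## Numerical choices and limitations

- Concentrations use N_A = 6.02214076×10²³; µM = copies/(602.2·V[µm³]).
- Counts round-trip through reports bit-exactly (written via `repr`);
  table floats are written to 10–12 significant digits.
- The calibration recovery check compares the mean estimate over 200
  noisy replicates against the mean per-fit OLS standard error; with
  20% multiplicative iBAQ noise the errors-in-variables attenuation
  (~4% at most) stays well inside a single fit's standard error.
- The hard-sphere distance formula is itself an approximation at
  moderate φ: at φ = 0.1 it sits ~4% above the insertion oracle, well
  inside the 15% band appropriate for that approximation.
- Organelle-specific published copy numbers depend on curated species
  tables (supplementary material of the respective studies); the
  package reproduces the *math* that produces them, and its shipped
  defaults are synthetic study conditions, not those curated tables.
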