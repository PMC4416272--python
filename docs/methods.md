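# Methods

## The question the package answers

A total merit index (TMI) combines estimated breeding values (EBV) of
several traits into one selection criterion.  When the trait EBV come from
one multitrait BLUP on all phenotypes, the combination is trivially
consistent.  Routine evaluations instead produce per-trait EBV and combine
them afterwards — either through approximate two-step multitrait models on
condensed pseudo-records, or through selection-index weighting that must
neglect residual covariances between traits.  `meritsim` measures, on
simulated data where the truth is known, how far each shortcut falls from
the multitrait reference: rank agreement, bias by reliability class and
birth cohort, realized versus estimated reliability, variance inflation,
and the implied loss in selection response.

## Simulated population

Five traits (FY, PY, NDG, SCC, NRR) follow a multivariate normal additive
model with heritabilities 0.40/0.39/0.27/0.12/0.02, unit genetic SDs and
genetic correlations (FY,PY)=0.85, (FY/PY,NDG)=0.10, (FY/PY,SCC)=0.25,
(FY/PY,NRR)=−0.20, (SCC,NRR)=−0.10.  Economic weights per additive genetic
SD are 5.4/53.6/4.3/19.7/17 %.  Since weights are per genetic SD, all
comparison statistics are invariant to trait scaling, and unit SDs lose no
generality.  Residual scenarios set residual correlations to a fraction
(0, 0.5, 1.0) of the genetic correlations; residual variances always follow
from the heritabilities.

The breeding scheme is a closed progeny-testing population: herds of 30
cows; every female records FY, PY, SCC, NRR once at age two in her herd-year
contemporary group; 60 % of males record NDG at age one.  There are no
repeated records.  Each year the scheme re-runs a full 5-trait BLUP on all
records to date, ranks candidates on the TMI, keeps the top replacement
heifers (cows stay four years, one offspring per cow and year, 50:50 sex
ratio), and mates 25 % of cows to young (unproven) bulls and 75 % to proven
bulls (bulls with a configured number of recorded daughters).  True breeding
values are transmitted as parent average plus Mendelian sampling with
covariance ½(1 − (F_s+F_d)/2)·G0, with inbreeding tracked exactly.
Herd-year effects are i.i.d. normal with SD equal to half the phenotypic SD
— their only role is to exercise the fixed-effect estimation, and any
non-degenerate spread does that.

Randomness is split into three independent streams (genetic, residual,
selection) derived from one seed.  A replicate's phenotype *structure* and
standard-normal residual draws are scenario-independent; phenotypes for any
residual scenario are obtained by colouring the draws with that scenario's
Cholesky factor, so scenarios can share pedigree and true breeding values
exactly when desired.  The comparison pipeline, however, simulates each
scenario with selection on its own phenotypes: if selection were driven by
another scenario's data, the reference evaluation would condition on
information outside its model and acquire a visible trend bias, which is
exactly the artefact the reference must not have.

### What the simulator does and does not emulate

It reproduces the features the method comparison is sensitive to:
sex-limited single records, contemporary groups, overlapping generations,
progeny-tested versus young sires, a strong selection trend, and
accumulating inbreeding.  It does not attempt herd dynamics (culling on
yield, seasonal calving), repeated lactations, genomic information, or the
exact sire-usage pattern of any national scheme.  Conclusions about the
*relative* behaviour of the four TMI methods transfer; absolute trend or
reliability levels do not.

## Evaluations

All models are animal models solved from Henderson's mixed model equations
with one fixed factor per trait — herd-year for phenotypes, birth-year for
second-step pseudo-records, a general mean for de-regression.  Every such
factor partitions its records, so the fixed block is full rank and no
constraint is needed; a useful corollary is that precision-weighted
residuals sum to zero within every level, which makes the de-regression
below exactly consistent.  Missing traits enter through the inverse of the
``R0`` submatrix of each animal's observed traits; per-record weights `w`
scale residual precision as `diag(√w) R0⁻¹ diag(√w)`.

Systems are solved by sparse LU on a fill-reducing ordering computed on the
collapsed animal graph (one node per animal, trait blocks kept contiguous),
or by Jacobi-preconditioned conjugate gradients above 300k equations, to a
relative residual of 1e-10 (1e-8 inside the yearly selection loop, where
only the ranking matters).  Prediction-error variances are exact: an
up-looking LDLᵀ factorization on the symbolic fill pattern feeds the
Takahashi recurrences, whose clique structure closes on that pattern; the
densely-filled trailing block of the factor (heavily used sires and their
mates) is inverted with dense BLAS instead of the scalar recursion, which
is exact for any split point.  Small systems fall back to a dense inverse.
Reliabilities are `r² = 1 − PEV/(σ²_a(1+F))`, clipped to [0, 1).

### Two-step methods

Yield deviations are `y* = y − Xb̂` with `b̂` from the univariate first
step.  Second-step record weights are effective own performances,
`EOP = α/(1−r²_own) − α` with `r²_own = n h²/(1+(n−1)h²)` the reliability
of the animal's own records — exactly 1 for the single records simulated
here.  De-regression solves, per trait, for pseudo-observations that
reproduce the univariate EBV when re-evaluated under a weighted mean-only
animal model; because the first-step fixed factor partitions the records,
the defining identity

    (w_i/σ²_e)(y°_i − μ) = [(W/σ²_e + A⁻¹/σ²_a) û]_i

is exactly consistent and the round trip holds to solver precision (a
verification solve guards it).  The de-regression weights default to the
same own-performance record equivalents as the second step, so both stages
agree on each pseudo-record's information content; daughter-equivalent EDC
weights (`(4−h²)/h² · r²/(1−r²)` on the own-information reliability, i.e.
the full reliability with the parent-average contribution removed) are
implemented and available (`run_methods(drp_weights="edc")`) for data where
pseudo-records must carry progeny information, at the cost of double
counting progeny when those progeny are in the model themselves.

### Selection index

Univariate EBV are combined per animal with weights `b = P*⁻¹ G* v`,
`v_t = ω_t/σ_a,t`, where `P*` has diagonal `r²_i σ²_a,i` and off-diagonals
`r_g,ij r²_i r²_j σ_a,i σ_a,j` (residual covariances neglected, reliability
products on the r² scale; an accuracy-scale `r_i r_j` variant is available
behind a flag) and `G*_ij = r²_i r_g,ij σ_a,i σ_a,j`, so the diagonal case
collapses to the univariate regression of true on estimated breeding value.
Index reliability is `b'G*v / v'G0v`.  `P*` is ridge-regularized
(1e-8·σ²_a on the diagonal) when its condition number exceeds 1e12, which
only triggers for animals with vanishing reliabilities.

### Standardization

Each method's raw index is mapped to `100 + 12(x − mean_base)/σ_T,base`,
where the base cohort is birth years 18–22 and `σ_T,base` is the SD of the
*true* aggregate genotype in that cohort — a population parameter, not the
raw EBV spread; using the EBV spread would absorb exactly the inflation the
comparison measures.  When truth is unavailable the scale falls back to the
raw SD deflated by the square root of the mean reliability.

## Comparison statistics

All statistics are restricted to birth years 11–30, computed per replicate
and then averaged (dispersion reported alongside).  Groupings: reliability
classes `<39 … >90` on the reference TMI reliability ×100; 5-year birth
cohorts; and bulls/females with/without at least one phenotyped offspring
(BP/BNP/FP/FNP).  Cells under 10 animals are flagged, not computed.
Spearman correlations use average ranks; realized reliability is the
squared Pearson correlation of estimated with true TMI (×100); expected SD
is `√(r²σ²_T)` with `σ_T` the true within-group SD; selection-response loss
is `100(√r²_SI − √r²_MULTI)`, the response difference under the breeder's
equation when intensity, interval and genetic SD are held fixed.

## Problem sizes

The shipped configurations are desk-scale choices: the reproduction script
and acceptance tests use 20 herds × 30 cows over 30 years (≈19,000 animals
and 95,000 mixed-model equations per replicate), two replicates, scenarios
0 and 2; examples and unit tests use 12 herds.  A `scaled()` preset
(200 × 30, three replicates) and a cluster-scale `full_scale()` preset
(1,710 × 30, ten replicates) are provided for larger studies.  Sire numbers
in the desk presets are set to keep proven-bull daughter groups realistic
(tens of daughters per year) rather than to scale bull counts
proportionally — high-reliability proven bulls are the defining feature of
a progeny-testing scheme and several comparison statistics live in those
classes.  Two consequences of the reduced scale are worth knowing: the
highest reliability classes hold only a dozen bulls (and `>90` may be
empty), so class-level statistics there carry the bias-magnitude noise of
small cells and the steep desk-scale trend; and cohort-mean prediction
errors drift by up to ±1 standardized point per replicate, so the reference
method's bias against truth is zero only in expectation, with visible
replicate noise in the earliest cohorts.

## Numerical choices

Convergence tolerance 1e-10 (relative residual) for all reported
evaluations — rank correlations near 1.000 need EBV noise far below the
reporting precision.  Ties in selection ranking break deterministically by
animal id.  The de-regression drops zero-weight animals (they contribute
through the relationship matrix only); pseudo-record sets reject animals
outside the pedigree.  Degenerate inputs — non-positive-definite
covariance matrices, reliabilities outside [0, 1), empty base cohorts,
cyclic or mis-sexed pedigrees — are rejected with diagnostics naming the
offending entry.
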