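# Methods

## The indicator

Net Primary Production Use (NPPU, synonym Biotic Resource Use) quantifies
how much primary production an ingredient appropriates. For a fresh
organism of trophic level TL in a food web with trophic transfer
efficiency TE, each trophic step dilutes production by a factor TE, so
sustaining 1 kg of the organism's carbon requires (1/TE)^(TL−1) kg of
primary-production carbon:

    NPPU [g C / kg product] = C_content [g C / kg] × (1/TE)^(TL−1)

The kg C/kg representation is always derived by an exact division by 1000;
`NPPUValue` stores g C/kg and exposes kg C/kg as a property so the two
published unit columns cannot drift.

Conventions adopted where sources are loose: the carbon term is the carbon
content of one kilogram of product on a fresh (wet) basis for animal
classes — consistent with the generic constant of 111.1 g C per kg of
fresh fish — and dry-matter inputs must be converted on read. TE is a
fraction internally; percent is strictly an I/O representation.

## Carbon stoichiometry

Carbon content is a linear combination of the proximate fractions
(g/kg as-fed) with the carbon mass fractions of representative empirical
formulas, computed from the integer molar masses C = 12, H = 1, O = 16,
N = 14 (not IUPAC weights — the integers are what reproduce the published
three-decimal constants exactly):

| fraction     | formula    | carbon mass fraction |
|--------------|------------|----------------------|
| protein      | C₅H₇O₂N    | 60/113 → 0.531       |
| lipid        | C₅₇H₁₀₄O₆  | 684/884 → 0.774      |
| carbohydrate | C₆H₁₀O₅    | 72/162 → 0.444       |

The carbohydrate coefficient deserves a note: the five-carbon unit C₅H₈O₄
sometimes quoted alongside these formulas gives 60/132 = 0.4545, which is
inconsistent with the 0.444 constant actually used in reference datasets;
0.444 is the anhydroglucose (C₆H₁₀O₅) fraction. `default_carbon_coefficients`
returns the canonical triple (0.531, 0.774, 0.444); both formulas are
exported (`ANHYDROGLUCOSE_FORMULA`, `PENTOSAN_FORMULA`) so users can
recompute either at full precision.

Carbohydrate, when absent from a source table, is taken **by difference**:
the as-fed remainder after protein, lipid, ash and moisture, floored at
zero. Compositions must close to 1000 g/kg within 1 g/kg; a redundant
dry-matter column is validated against moisture at the same tolerance.

Plant ingredients are primary producers (TL = 1): the amplification factor
is identically 1 and NPPU in g C/kg equals the carbon content. Milk-based
ingredients are computed directly on the final ingredient's composition
with TL fixed at 2.

## Tiers

A tier is a declared contract about parameter provenance, encoded as a
`TierPolicy` (te_source, c_source, tl_source):

* marine — T1 (generic TE = 10 %, generic C = 111.1 g/kg), T2 (ecosystem
  TE, generic C), T3 (ecosystem TE, measured C); TL is species-specific in
  all three;
* freshwater — T1 as above, T2 (generic TE, measured C);
* other animals — one tier (generic TE, measured C, specific TL);
* milk — TL fixed at 2, generic TE, carbon from the composition;
* plant — TL fixed at 1.

A record lacking a value its tier marks "specific" raises
`MissingDataError` naming the field: silently downgrading a tier would
mislabel outputs. One deliberate softening: when a policy demands specific
carbon and the record carries a proximate composition but no measured
C value, the carbon content is derived stoichiometrically from the
composition — that is precisely how the milk class is defined, and it is a
derivation, not a downgrade.

## Coproduct allocation

Reducing 1 kg of fresh fish yields Y_m kg of meal and Y_o kg of oil.
Energy allocation splits the fresh burden by energy shares,

    NPPU_meal = (NPPU_fresh / Y_m) · Y_m E_m / (Y_m E_m + Y_o E_o),

and symmetrically for oil. Mass allocation gives both coproducts the same
per-kg value NPPU_fresh / (Y_m + Y_o) — the unique mass-proportional rule
satisfying the same mass balance. Custom allocation substitutes user
weights (e.g. prices) for the energy densities; equal weights recover mass
allocation, and no price table is shipped. Every method satisfies
Σ yieldᵢ·NPPUᵢ = NPPU_fresh to 1e−9 relative; the residual fraction
(1 − Y_m − Y_o, stickwater and losses) carries no burden.

`tier_yield_matrix` crosses the tiers with generic vs. specific yields:
six labelled variants (T11…T32) for marine records, four (T11…T22) for
freshwater. Package-default generic values — yields 0.225 / 0.05, gross
energies 20.0 / 39.5 MJ/kg — are conventional reduction-industry numbers,
used only by fixtures and CLI defaults; all computations take the
coproduct spec as an explicit input.

## Uncertainty

First-order Taylor propagation with independent inputs:

    σ_NPPU² = (∂N/∂C · σ_C)² + (∂N/∂TE · σ_TE)² + (∂N/∂TL · σ_TL)²
    ∂N/∂C  = (1/TE)^(TL−1)
    ∂N/∂TE = −C (TL−1) TE^(−TL)
    ∂N/∂TL = C (1/TE)^(TL−1) ln(1/TE)

Reference species tables typically publish only a trophic-level SD, so
σ_C and σ_TE default to zero. `monte_carlo_sd` cross-checks the
linearization with independent normal perturbations truncated to the valid
domain (C ≥ 0, 0 < TE ≤ 1, TL ≥ 1), rejection-sampled; it warns when more
than half the raw draws are rejected, since heavy truncation biases the
estimate.

Accuracy of the linearization: the TL perturbation enters exponentially,
so the exact (lognormal-like) SD exceeds the first-order value by roughly
¾·(σ_TL·ln(1/TE))² in relative terms. At the generic configuration
(TE 10 %, TL 2) with all input CVs at 5 % this systematic gap is already
≈ 5 %, i.e. the 5 %-agreement check between Taylor and Monte-Carlo sits at
the edge of its own regime; at 1–2 % CVs the two agree to ~1 %. At high
trophic levels (TL ≳ 3) the convexity dominates and the Taylor SD
understates the simulated SD by 10 % or more even at modest CVs — SD
values for high-TL species should be read as first-order approximations,
and users with better input data should re-propagate.

## Dataset I/O

Nine schemas cover the published file family (the three marine fresh-tier
files share one schema, as do the two freshwater ones). Headers are mapped
by name, order-insensitively, to internal snake_case identifiers; percent
composition columns become g/kg (×10), TE becomes a fraction (a value
above 1 is read as percent — the only ambiguity, TE = 1, is a valid
fraction). The reader sniffs comma-vs-semicolon delimiters with the
matching dot-vs-comma decimals; the writer always emits canonical
comma/dot/UTF-8 and re-derives every kg/kg NPPU column from its g/kg
sibling, so emitted pairs are exactly consistent. Validation returns
row-level findings (never exceptions): NPPU unit-pair consistency within
0.5 g/kg, TE ∈ (0, 1], TL ≥ 1, composition percentages in [0, 100] summing
to ≤ 101, non-negative SDs.

The processed-ingredient layouts (allocated variant columns) are a
canonical self-consistent design: published descriptions of those files
give grouped column counts that do not reconcile with their own totals, so
bit-compatibility with deposited files is not claimed; the fresh-organism,
plant, milk and SD layouts follow the published column lists.

## Synthetic fixtures

The generator emulates the input side of the reference tables: TL, TL_SD
and TE drawn uniformly from plausible ranges (TL 2.0–4.5, TE 3.51–38.1 %,
TL_SD 0–0.5), moisture 60–80 % with a protein-heavy Dirichlet partition of
the dry remainder closing the 1000 g/kg budget exactly (so carbohydrate by
difference is exercised at its boundary), and coproduct specs with meal
yields 15–30 %, oil yields 2–12 %, gross energies 18–22 / 35–42 MJ/kg.
Uniform sampling is deliberate — the literature gives ranges, not fitted
distributions. What the fixtures do **not** emulate: correlations between
TL and body composition, ecosystem-level TE structure, measurement error
in source compilations, and real species identities; tests passing on
fixtures therefore demonstrate the computational contracts (identities,
round trips, monotonicity), not agreement with any published per-species
value, which depends on third-party data compilations.

## Numerical choices and limitations

* Closure and dry-matter tolerances: 1 g/kg; NPPU unit-pair tolerance:
  0.5 g/kg; allocation mass balance: 1e−9 relative.
* Gradient verification: central differences, relative step 1e−6,
  tolerance 1e−5 relative.
* Monte-Carlo: default 10⁵ draws (SD estimate stable to ~0.3 %), seeded
  `numpy` Generator, rejection warning threshold 50 %.
* Degenerate inputs: TL = 1 gives amplification exactly 1 and σ_NPPU = σ_C;
  all-zero sigmas short-circuit to exactly 0.
* Test and acceptance problem sizes (1000 random coproduct specs, 100
  five-row tables, 10⁵ draws) were chosen as the smallest sizes at which
  the checked identities are exercised across their parameter ranges; the
  whole suite runs in a few seconds.
* Economic allocation is intentionally not shipped (price volatility);
  `allocate_custom` is the hook for user-supplied value shares.
* Multi-stage allocation of milk coproducts across dairy value chains is
  out of scope.
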