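"""Published reference values for the rhesus macaque trio study design.

These constants are the printed estimates from the 19-trio rhesus macaque
(Macaca mulatta) pedigree study whose design this package models.  They
serve as simulation defaults, worked-example inputs, and cross-check
constants; none of them is derived from data shipped with the package.
"""

from __future__ import annotations

from .parental import ParentAgeModel

#: Per-parent mutation-count regression (identity link), counts per trio:
#: maternal = 4.6497 + 0.3042 * age, paternal = 4.8399 + 1.8364 * age.
COUNT_MODEL = ParentAgeModel(
    maternal_intercept=4.6497,
    maternal_slope=0.3042,
    paternal_intercept=4.8399,
    paternal_slope=1.8364,
    link="identity",
)

#: Poisson (log-link) variant of the per-parent count regression.
COUNT_MODEL_LOG = ParentAgeModel(
    maternal_intercept=1.62,
    maternal_slope=0.04,
    paternal_intercept=2.48,
    paternal_slope=0.07,
    link="log",
)

#: False-positive rate of surviving candidates (from manual curation).
BETA = 0.1089
#: False-negative rate of the allelic-balance + variant-site filters.
ALPHA = 0.0402
#: Mean callable autosomal sites per trio.
CALLABLE_SITES = 2_351_302_179

#: Candidate counts: 744 survivors across 19 trios, 663 after curation.
TOTAL_CANDIDATES = 744
CURATED_CANDIDATES = 663
N_TRIOS = 19
PHASED_MUTATIONS = 337
TRANSITIONS = 448

#: Chimpanzee validation trio.
CHIMP_CALLABLE_SITES = 1_966_477_569
CHIMP_ALPHA = 0.046
CHIMP_CANDIDATES = 54
CHIMP_CANDIDATES_CURATED = 47

#: Nucleotide diversity of wild Indian rhesus macaques.
PI = 0.00247
#: Generation time and mean wild reproduction ages (years).
GENERATION_TIME = 11.0
AGE_MATERNAL_WILD = 10.0
AGE_PATERNAL_WILD = 12.0
#: Mean ages at conception in the sequenced captive pedigree.
AGE_MATERNAL_CAPTIVE = 8.4
AGE_PATERNAL_CAPTIVE = 12.4
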