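"""Stage labels and the closed catalogue of server-visible payload kinds.

Any message whose kind is outside CATALOGUE constitutes a privacy violation:
the server may only ever observe masked count/moment sums, two-sided
obfuscated projection payloads, the Level-0 ADMM inputs, encoded association
test vectors, study-level public dimensions, and the encoded returns it sends
back.  None of these reveals raw data or true (unpadded) per-node dimensions.
"""

STAGE_QC = "qc"
STAGE_MOMENTS = "moments"
STAGE_PROJECTION = "projection"
STAGE_LEVEL0 = "level0"
STAGE_ASSOCIATION = "association"
STAGE_RESULT = "result"

# node -> server
MASKED_COUNTS = "masked_counts"
MASKED_MOMENTS = "masked_moments"
PUBLIC_DIMS = "public_dims"
PROJ_Z = "proj_Z"
PROJ_X = "proj_X"
PROJ_Y = "proj_y"
L0_GRAM = "l0_gram"
L0_DESIGN = "l0_design"
L0_PHENO = "l0_pheno"
ASSOC_TEST = "assoc_test"

# server -> node (encoded returns)
SUM_COUNTS = "sum_counts"
SUM_MOMENTS = "sum_moments"
PROJ_X_RESULT = "proj_X_result"
PROJ_Y_RESULT = "proj_y_result"
RESULT_CHISQ = "result_chisq"

CATALOGUE = frozenset(
    {
        MASKED_COUNTS,
        MASKED_MOMENTS,
        PUBLIC_DIMS,
        PROJ_Z,
        PROJ_X,
        PROJ_Y,
        L0_GRAM,
        L0_DESIGN,
        L0_PHENO,
        ASSOC_TEST,
        SUM_COUNTS,
        SUM_MOMENTS,
        PROJ_X_RESULT,
        PROJ_Y_RESULT,
        RESULT_CHISQ,
    }
)
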