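"""Bundled reference tables for worked examples.

``pan_cancer_benchmark`` returns the published UK Biobank pan-cancer PRS
benchmark for 17 prevalent cancers: test-set ROC and PR AUCs (percent) of
per-disease single-task models and of two multi-task models (one trained on
all cancers, one on all diseases), the printed relative-increase cells, and
trait prevalences.  It is used to exercise the transfer statistics
(:func:`linaprs.training.relative_increase`, column aggregates) on real
printed numbers.

Note: a few printed relative-increase cells were evidently computed from
unrounded AUCs (e.g. malignant melanoma pan-cancer ROC prints +234% where
the rounded AUCs give +229%), so cells only reproduce from the AUC columns
up to that rounding provenance.
"""

from __future__ import annotations

import io

import pandas as pd

_PAN_CANCER_TSV = """\
disease	stl_roc	pan_cancer_roc	pan_cancer_roc_rel	pan_disease_roc	pan_disease_roc_rel	stl_pr	pan_cancer_pr	pan_cancer_pr_rel	pan_disease_pr	pan_disease_pr_rel	prevalence
Malignant melanoma	52.80	59.20	234	58.10	194	1.33	1.70	790	1.61	593	1.28
Non-melanoma skin cancer	61.50	62.40	8	62.90	12	9.76	10.03	8	10.21	14	6.65
Skin cancer	61.00	61.80	7	61.90	8	10.40	10.73	11	10.86	15	7.32
Lung cancer	59.10	60.30	14	60.50	16	1.39	1.44	11	1.51	23	0.90
Intrathoracic cancer	59.10	60.70	18	61.00	21	1.54	1.58	7	1.65	20	1.01
Colorectal cancer	54.40	56.40	46	57.10	60	2.00	2.21	71	2.29	100	1.72
Colon cancer	53.90	55.70	47	56.10	59	1.38	1.49	51	1.49	53	1.17
Rectal cancer	54.70	57.90	69	59.30	100	0.77	0.88	98	0.89	116	0.67
Bladder cancer	64.50	67.90	24	68.40	27	0.80	0.87	24	0.92	42	0.51
Uterine cancer	51.20	53.20	177	51.80	50	1.08	1.18	224	1.10	49	1.04
Cervical cancer	55.20	55.40	4	56.50	24	1.80	1.88	35	1.97	76	1.58
Prostate cancer	60.00	59.70	-3	59.60	-4	8.33	8.53	9	8.37	2	6.06
Breast cancer	57.00	58.30	19	58.10	16	9.38	9.67	13	9.79	20	7.25
Female genital tract cancer	54.00	54.30	7	54.50	11	3.15	3.27	41	3.39	84	2.86
Male genital tract cancer	53.60	56.10	68	54.50	24	2.57	2.73	57	2.59	9	2.28
Lymphoma	50.40	56.80	1442	57.90	1704	0.73	0.82	102	0.82	98	0.64
Non-hodgkins lymphoma	52.10	56.60	220	57.80	278	0.61	0.68	81	0.69	95	0.53
"""

# Published decoy/real SNP counts at the melanoma 5% FDR threshold in the
# decoy-augmented pan-cancer model (importance score 0.52e-3).
MELANOMA_FDR_EXAMPLE = {"n_decoy_above": 3091, "n_real_above": 59350}


def pan_cancer_benchmark() -> pd.DataFrame:
    """The 17-cancer AUC benchmark table (values in percent)."""
    return pd.read_csv(io.StringIO(_PAN_CANCER_TSV), sep="\t")
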