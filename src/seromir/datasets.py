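"""Bundled reference data.

A small published reference table from a serum miRNA screen in alcohol use
disorder (20 cases vs 10 age-matched controls): the 16 miRNAs whose
sequencing-based group difference was nominally significant with a
directionally consistent microarray change, with per-platform percent
changes and p-values and the control/case mean RPM values.  Used to
validate the percent-change arithmetic, the cross-platform concordance
statistic, and the tier rules against published numbers.
"""

from __future__ import annotations

import io

import pandas as pd

# symbol, control RPM, case RPM, seq %change, seq p, array %change, array p
_SCREEN_TSV = """\
symbol	ctrl_rpm	aud_rpm	seq_pct_change	seq_p	array_pct_change	array_p
mir-96	24.6	11.3	142.6	0.031	15.0	0.059
mir-320b-1	61.0	144.6	137.1	0.004	22.2	0.071
mir-1976	4.1	9.9	138.1	0.039	24.1	0.081
mir-24-1	31.3	90.5	189.4	0.008	6.2	0.338
mir-30a	108.2	209.9	94.0	0.014	5.1	0.860
mir-92b	7141.9	4553.8	-36.2	0.016	-8.2	0.312
miR-96-5p	111.7	252.0	125.5	0.018	8.0	0.455
mir-127	68.6	158.9	131.5	0.021	8.4	0.455
mir-136	4.4	9.7	121.2	0.035	1.5	0.760
miR-301a-3p	205.9	85.1	-58.7	0.045	-2.4	0.878
mir-320b-2	61.3	148.8	142.9	0.004	5.2	0.333
mir-421	15.5	30.3	95.6	0.020	9.0	0.725
miR-660-5p	196.9	99.7	-49.4	0.028	-10.2	0.451
mir-671	14.8	44.4	200.0	0.003	4.2	0.692
mir-3615	50.1	78.3	56.4	0.031	1.3	0.881
mir-3676	2.1	11.1	437.1	0.027	12.9	0.218
"""


def published_screen() -> pd.DataFrame:
    """The 16-row published cross-platform screen table.

    Note: for two rows (mir-96 and mir-1976) the printed RPM pair is not
    arithmetically consistent with the printed percent change (typesetting
    artifacts in the source table); the percent-change columns are the
    authoritative effect sizes and the RPM columns are kept as printed.
    """
    df = pd.read_csv(io.StringIO(_SCREEN_TSV), sep="\t")
    return df
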