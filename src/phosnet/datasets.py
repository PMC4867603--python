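"""Bundled reference tables."""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: published counts of quantified phosphopeptides by phosphosite multiplicity
#: in the adipose high-fat-diet study this pipeline reimplements downstream
#: analysis for: 7,696 peptides total at 1% FLR
PUBLISHED_MULTIPLICITY_COUNTS = {1: 6849, 2: 787, 3: 60}


def regulated_metabolic_sites() -> pd.DataFrame:
    """Published differentially regulated metabolic-enzyme phosphosites.

    Natural-log fold changes (HFD vs LFD) and FDR q-values for the
    down-regulated metabolic-enzyme sites reported by the adipose study;
    used as a worked example for the classification filter and fold-change
    conversion.
    """
    ref = resources.files("phosnet").joinpath("data/regulated_metabolic_sites.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
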