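"""Bundled worked-example tables."""

from importlib import resources

import pandas as pd


def load_brca_examples() -> pd.DataFrame:
    """Worked-example CNS/PNS pairs for nine drug-pathway matches in breast
    invasive carcinoma (BRCA), from a published pan-cancer prescription
    analysis.

    Columns: drug, pns, cns, effect (Enrichment/Depletion of the pathway in
    the tumor), ps_printed (the published prescription score), pathway, and
    ps_decimals (the rounding at which ps_printed was reported).
    """
    with resources.files("cdp.data").joinpath("brca_example_scores.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
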