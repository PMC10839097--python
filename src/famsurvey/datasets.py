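"""Bundled reference datasets for the Coptis teeta C2H2-ZFP family.

Two small published tables ship with the package: the qPCR primer panel
for six family genes (sequences, annealing temperatures, GC content,
amplicon sizes) and the Ka/Ks estimates reported for the family's
eleven duplicated gene pairs (two tandem, nine segmental). They serve
as worked inputs for the primer-QC and selection-classification paths.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("famsurvey.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_primer_panel() -> pd.DataFrame:
    """qPCR primer panel: gene, direction, sequence, anneal_temp_c,
    gc_percent, amplicon_bp."""
    return _load("qpcr_primers.tsv")


def load_duplicated_pair_kaks() -> pd.DataFrame:
    """Reported Ka/Ks for the family's duplicated gene pairs:
    gene1, gene2, ka, ks, ka_ks, mode, negative_selection."""
    return _load("duplicated_pair_kaks.tsv")
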