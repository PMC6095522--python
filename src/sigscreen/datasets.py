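"""Packaged example data.

The shipped Nrf2-style biomarker table is *synthetic*: it reproduces the
published composition of the oxidative-stress biomarker (75 probe sets,
52 up- and 23 down-regulated, collapsing to 48 genes) with plausible
mouse liver gene symbols and fold-changes, but it is generated, not the
supplementary table of any study.  It exists so the screen, the worked
examples and the command-line demos run without downloads.
"""

from __future__ import annotations

from importlib import resources

from .core_io import Biomarker, read_biomarker

_FILENAME = "nrf2_biomarker_synthetic.tsv"


def load_nrf2_biomarker() -> Biomarker:
    """The packaged synthetic Nrf2-style biomarker (75 probes / 48 genes)."""
    with resources.as_file(resources.files("sigscreen.data").joinpath(_FILENAME)) as p:
        return read_biomarker(p, name="Nrf2")
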