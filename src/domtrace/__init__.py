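"""domtrace: molecular-fingerprint analysis of dissolved organic matter.

Pipeline stages: centroided peak-list I/O and blank subtraction
(:mod:`~domtrace.peak_io`), CHNOS formula assignment
(:mod:`~domtrace.formula_engine`), molecular descriptors and van Krevelen
classes (:mod:`~domtrace.descriptors`), two-treatment molecular fate
(:mod:`~domtrace.fate`), paired-mass-distance reactomics
(:mod:`~domtrace.reactomics`), interpretable gradient-boosted fate models
(:mod:`~domtrace.ml_explain`) and a ground-truthed synthetic-data generator
(:mod:`~domtrace.synthetic_data`).
"""

from importlib.resources import files as _files

import pandas as _pd

__version__ = "0.1.0"

__all__ = ["load_reference_summary", "__version__"]


def load_reference_summary() -> "_pd.DataFrame":
    """Published per-sample molecular metrics of coal-derived DOM leachates.

    One row per coal rank (long-flame coal, lean coal, anthracite) and
    temperature treatment (25 °C / 50 °C): total formula count, counts per
    elemental class, and intensity-weighted mean metrics.  Used as a
    consistency reference for the summary computations.
    """
    path = _files("domtrace").joinpath("data/coal_dom_reference_summary.csv")
    return _pd.read_csv(path)
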