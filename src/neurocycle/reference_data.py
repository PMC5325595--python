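"""Published worked-example data used as pipeline inputs.

``COMMON_ENRICHMENT_LOG2_FOLDS`` holds the published log2 fold-enrichment
values (each circadian neuron group vs the dopaminergic TH outgroup) for
the transcripts reported as commonly enriched in *Drosophila* circadian
neurons.  ``None`` marks LR ("low reads") cells: the transcript failed the
10-RPM expression filter in that group, so the cell cannot qualify toward
the enrichment rule.  The rows are already vetted for statistical
significance, so the rule engine is applied to them with the statistical
gate disabled.
"""

from __future__ import annotations

import pandas as pd

CIRCADIAN_VS_TH_COLUMNS = ("LNv", "LNd", "DN1")

# gene -> (log2 fold LNv vs TH, LNd vs TH, DN1 vs TH); None = LR
COMMON_ENRICHMENT_LOG2_FOLDS: dict[str, tuple[float | None, float | None, float | None]] = {
    "cry": (4.04, 2.78, 4.11),
    "vri": (3.75, 2.68, 2.93),
    "tim": (2.98, 2.43, 2.83),
    "npf": (4.54, 4.46, 6.51),
    "CG17777": (6.48, 6.46, 5.81),
    "CG13054": (6.35, 6.36, 6.80),
    "Tdc2": (4.10, 3.23, 3.56),
    "vib": (3.91, 2.76, 4.37),
    "Tbh": (4.94, 2.33, 2.09),
    "Hr51": (3.90, 3.37, 1.00),
    "CG11221": (2.40, 2.54, 1.02),
    "per": (2.34, None, 3.01),
    "Clk": (3.33, None, 3.80),
    "Pdfr": (3.32, None, 4.79),
    "Dh31": (4.08, 0.28, 4.04),
    "MCPH1": (2.84, 0.78, 2.43),
    "CG31714": (2.81, 0.77, 2.78),
    "CG6912": (None, 8.54, 8.31),
}

#: A synthetic distractor that fails the >= 5-fold-in-two-groups rule
#: (folds 3.0x / 0.5x / 0.5x): only one cell reaches log2(5).
SYNTHETIC_DISTRACTOR_ROW = ("synthetic_distractor", (1.58, -1.0, -1.0))


def common_enrichment_table(include_distractor: bool = False) -> pd.DataFrame:
    """The published fold table as a genes x groups DataFrame (NaN = LR)."""
    data = {g: list(v) for g, v in COMMON_ENRICHMENT_LOG2_FOLDS.items()}
    if include_distractor:
        name, folds = SYNTHETIC_DISTRACTOR_ROW
        data[name] = list(folds)
    df = pd.DataFrame.from_dict(data, orient="index",
                                columns=list(CIRCADIAN_VS_TH_COLUMNS))
    df.index.name = "gene_id"
    return df.astype(float)
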