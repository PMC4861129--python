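"""Internal-standard normalization of targeted-metabolomics abundances.

Each chromatography method carries its own spiked internal standards.  For
every sample, each metabolite is divided by the median abundance of its
method's internal standards in that sample, which cancels per-sample,
per-method instrument scale.  The ratios are then log2-transformed and each
metabolite row is median-centered across samples.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import MetaboliteMatrix
from .exceptions import MetsigError

logger = logging.getLogger(__name__)


def normalize_metabolites(raw: MetaboliteMatrix) -> pd.DataFrame:
    """Normalize raw peak areas to a log2, median-centered matrix.

    Returns a DataFrame (metabolites x samples) in log2 units with a
    per-metabolite median of zero over non-missing samples; internal-standard
    rows are removed.  Zero raw values are replaced by half the smallest
    positive value of that metabolite before the log transform; missing
    values stay missing.

    Raises
    ------
    MetsigError
        If a method has no internal-standard row, a standard has missing
        values, or all of a sample's standards for a method are zero.
    """
    values = raw.values
    is_std = raw.is_internal_standard
    methods = raw.method

    std_rows = values.loc[is_std]
    if std_rows.isna().to_numpy().any():
        bad = std_rows.index[std_rows.isna().any(axis=1)].tolist()
        raise MetsigError(f"internal standard(s) with missing values: {bad}")

    normalized: dict[str, pd.Series] = {}
    for method in sorted(methods.unique()):
        method_mask = methods == method
        std_mask = method_mask & is_std
        if not std_mask.any():
            raise MetsigError(f"method '{method}' has no internal-standard row")
        scale = values.loc[std_mask].median(axis=0)  # per-sample scaling factor
        zero_samples = scale.index[scale <= 0].tolist()
        if zero_samples:
            raise MetsigError(
                f"all internal standards are zero for sample(s) {zero_samples} "
                f"in method '{method}'"
            )
        analyte_mask = method_mask & ~is_std
        for metabolite in values.index[analyte_mask]:
            row = values.loc[metabolite].copy()
            positive = row[row > 0]
            zeros = row == 0
            if zeros.any():
                if positive.empty:
                    logger.warning(
                        "metabolite %s is all-zero; left missing after normalization",
                        metabolite,
                    )
                    row[zeros] = np.nan
                else:
                    row[zeros] = positive.min() / 2.0
            normalized[metabolite] = np.log2(row / scale)

    out = pd.DataFrame(normalized).T.reindex(
        [m for m in values.index if not is_std.loc[m]]
    )
    out = out.sub(out.median(axis=1, skipna=True), axis=0)
    out.index.name = "feature_id"
    out.columns = values.columns
    return out
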