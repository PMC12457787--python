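"""Panel summary-table layouts and the bundled 24-cultivar grape dataset.

Two report layouts used throughout the pipeline:

- the per-cultivar read-count table with Total / Minimum / Average /
  Maximum footer rows (Average rounded half-up to the nearest integer);
- the per-stage preprocessing summary with survivor counts and the
  percentage of raw reads retained, at two decimals.

The package ships, as plain-TSV data, the published sequencing summary of a
24-cultivar grape panel profiled for three retrotransposon families
(VINE1, Gret1, Tvv1): raw read counts per cultivar and the preprocessing
stage counts. They serve as worked inputs for the layout arithmetic.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import pandas as pd

from tipprof.preprocess import ratio_percent


def round_half_up(x: Decimal | float) -> int:
    return int(Decimal(x).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def summarize_read_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Append Total / Minimum / Average / Maximum rows to a cultivar x family table."""
    if counts.empty:
        raise ValueError("empty count table")
    out = counts.copy()
    total = counts.sum()
    out.loc["Total"] = total
    out.loc["Minimum"] = counts.min()
    out.loc["Average"] = [round_half_up(Decimal(int(t)) / len(counts)) for t in total]
    out.loc["Maximum"] = counts.max()
    return out.astype(int)


def stage_ratio_table(stage_counts: pd.DataFrame) -> pd.DataFrame:
    """Recompute the ratio column (percent of the family's raw count, 2 dp).

    ``stage_counts`` needs columns family, stage, n_reads; the first stage
    of each family is taken as the raw denominator.
    """
    out = stage_counts.copy()
    ratios = []
    for fam, grp in out.groupby("family", sort=False):
        raw = int(grp["n_reads"].iloc[0])
        ratios.extend(ratio_percent(int(n), raw) for n in grp["n_reads"])
    out["ratio_percent"] = ratios
    return out


def load_grape24_read_counts() -> pd.DataFrame:
    """Bundled per-cultivar read counts (24 grape cultivars x 3 families)."""
    with resources.files("tipprof.data").joinpath("grape24_read_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="cultivar")


def load_grape24_stage_counts() -> pd.DataFrame:
    """Bundled preprocessing stage counts for the same panel (with printed ratios)."""
    with resources.files("tipprof.data").joinpath("grape24_stage_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
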