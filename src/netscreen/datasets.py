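"""Small reference tables shipped with the package."""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["islet_cluster_abundance"]


def islet_cluster_abundance() -> pd.DataFrame:
    """Reported per-cluster abundance statistics from a T2DM islet beta-cell
    single-cell comparison: 11 clusters with their Fisher-test p-value and
    condition-normalized proportion fold change (disease over control).

    Used as the worked example for the cluster selection rule
    (fc > 4 or fc < 0.25, p < 0.05).
    """
    with resources.files("netscreen.data").joinpath("islet_cluster_abundance.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
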