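"""Significance calling, DEG/DSD Venn partitioning, and percent change.

Default thresholds: |log2FC| >= 1 and -log10 p >= 1.3 (i.e. p <= ~0.05),
applied to raw p-values; BH q-values are carried alongside by the
differential table but do not drive the default calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LOG2FC_CUT = 1.0
NEGLOG10P_CUT = 1.3


def call_significant(log2fc, p, log2fc_cut: float = LOG2FC_CUT,
                     neglog10p_cut: float = NEGLOG10P_CUT):
    """Classify genes as up / down / ns.

    up: log2fc >= cut and -log10 p >= cut; down: log2fc <= -cut and the
    same p gate; everything else ns. Accepts scalars or vectors.
    """
    scalar = np.isscalar(log2fc) and np.isscalar(p)
    fc = np.atleast_1d(np.asarray(log2fc, dtype=float))
    pv = np.atleast_1d(np.asarray(p, dtype=float))
    if not np.isfinite(fc).all():
        raise ValueError("log2fc must be finite")
    if ((pv <= 0) | (pv > 1) | ~np.isfinite(pv)).any():
        raise ValueError("p-values must lie in (0, 1]")
    sig = -np.log10(pv) >= neglog10p_cut
    calls = np.where(sig & (fc >= log2fc_cut), "up",
                     np.where(sig & (fc <= -log2fc_cut), "down", "ns"))
    if scalar:
        return str(calls[0])
    if isinstance(log2fc, pd.Series):
        return pd.Series(calls, index=log2fc.index)
    return calls


@dataclass
class VennPartition:
    """Unique/common gene sets between the DEG and DSD calls of a contrast.

    Genes significant in opposite directions by the two metrics go to the
    ``discordant`` set rather than being silently dropped.
    """

    contrast: str
    deg_only_up: set = field(default_factory=set)
    deg_only_down: set = field(default_factory=set)
    dsd_only_up: set = field(default_factory=set)
    dsd_only_down: set = field(default_factory=set)
    common_up: set = field(default_factory=set)
    common_down: set = field(default_factory=set)
    discordant: set = field(default_factory=set)

    def counts(self) -> dict[str, int]:
        return {
            "deg_only_up": len(self.deg_only_up),
            "deg_only_down": len(self.deg_only_down),
            "dsd_only_up": len(self.dsd_only_up),
            "dsd_only_down": len(self.dsd_only_down),
            "common_up": len(self.common_up),
            "common_down": len(self.common_down),
            "discordant": len(self.discordant),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [(name, g) for name in
                ("deg_only_up", "deg_only_down", "dsd_only_up",
                 "dsd_only_down", "common_up", "common_down", "discordant")
                for g in sorted(getattr(self, name))]
        return pd.DataFrame(rows, columns=["set", "gene_id"])


def venn_partition(deg_calls: pd.Series, dsd_calls: pd.Series,
                   contrast: str = "") -> VennPartition:
    """Partition genes by which metric calls them significant, per direction."""
    if not deg_calls.index.equals(dsd_calls.index):
        if set(deg_calls.index) != set(dsd_calls.index):
            raise ValueError("DEG and DSD calls must share the same gene universe")
        dsd_calls = dsd_calls.reindex(deg_calls.index)
    deg_up = set(deg_calls.index[deg_calls == "up"])
    deg_down = set(deg_calls.index[deg_calls == "down"])
    dsd_up = set(dsd_calls.index[dsd_calls == "up"])
    dsd_down = set(dsd_calls.index[dsd_calls == "down"])
    discordant = (deg_up & dsd_down) | (deg_down & dsd_up)
    return VennPartition(
        contrast=contrast,
        deg_only_up=deg_up - dsd_up - discordant,
        deg_only_down=deg_down - dsd_down - discordant,
        dsd_only_up=dsd_up - deg_up - discordant,
        dsd_only_down=dsd_down - deg_down - discordant,
        common_up=deg_up & dsd_up,
        common_down=deg_down & dsd_down,
        discordant=discordant,
    )


def percent_change(control_mean: float, case_mean: float) -> float:
    """Signed percent change 100*(case - control)/control.

    Full precision is returned; round to the nearest integer for
    summary-style reporting.
    """
    if not control_mean > 0:
        raise ValueError("control mean must be positive for percent change")
    return 100.0 * (case_mean - control_mean) / control_mean
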