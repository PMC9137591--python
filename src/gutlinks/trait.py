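"""Spearman screen of genus abundance against individual body weight.

Within each sampling place the two body-weight groups are pooled (ten birds
with the study defaults) and every genus passing both inclusion filters —
mean relative abundance above 0.01% of the place's microbial population, and
non-zero in at least eight of the place's samples — is correlated with the
birds' individual body weight in grams. Significance is the raw two-sided
p < 0.05 (no multiplicity correction; that is the screen's stated rule, and
a known caveat). The p-value is exact (full enumeration) up to n = 8 and
the large-sample t approximation beyond.
"""

from __future__ import annotations

import logging

import pandas as pd

from .io import Config
from .network import exact_spearman

log = logging.getLogger(__name__)

COLUMNS = ["place", "genus", "rho", "p_value", "n_samples", "included", "reason"]


def bw_correlation_screen(
    rel: pd.DataFrame, meta: pd.DataFrame, config: Config | None = None
) -> pd.DataFrame:
    """Per-place Spearman correlation of each genus with body weight.

    ``rel`` is a genus x sample percent-abundance frame. Returns one row per
    (place, genus) with ``rho``, two-sided ``p_value``, sample count, an
    inclusion flag and, for excluded genera, a machine-readable reason
    (``abundance<=0.01%`` / ``prevalence<8``). Places with fewer samples
    than the prevalence minimum are skipped with an error log.
    """
    config = config or Config()
    min_prev = config.trait_min_prevalence
    min_mean_pct = config.trait_min_mean_abundance * 100.0
    rows = []
    for place in dict.fromkeys(meta["place"]):
        sub = meta[meta["place"] == place]
        samples = list(sub["sample_id"])
        if len(samples) < min_prev:
            log.error(
                "bw_correlation_screen: place %s has %d samples, fewer than the "
                "prevalence minimum %d; screen aborted for this place",
                place,
                len(samples),
                min_prev,
            )
            continue
        weights = sub.set_index("sample_id")["body_weight_g"]
        block = rel[samples]
        mean_pct = block.mean(axis=1)
        prevalence = (block > 0).sum(axis=1)
        for genus in rel.index:
            reason = None
            if not mean_pct[genus] > min_mean_pct:
                reason = f"mean_abundance<={min_mean_pct:g}%"
            elif prevalence[genus] < min_prev:
                reason = f"prevalence<{min_prev}"
            if reason is not None:
                rows.append(
                    {
                        "place": place,
                        "genus": genus,
                        "rho": float("nan"),
                        "p_value": float("nan"),
                        "n_samples": len(samples),
                        "included": False,
                        "reason": reason,
                    }
                )
                continue
            res = exact_spearman(
                block.loc[genus].to_numpy(), weights[samples].to_numpy()
            )
            rows.append(
                {
                    "place": place,
                    "genus": genus,
                    "rho": res.rho,
                    "p_value": res.two_sided_p,
                    "n_samples": res.n,
                    "included": True,
                    "reason": "",
                }
            )
    return pd.DataFrame(rows, columns=COLUMNS)


def significant_correlations(
    screen: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Included rows with two-sided p below ``alpha``, strongest first."""
    hits = screen[(screen["included"]) & (screen["p_value"] < alpha)]
    return hits.reindex(hits["rho"].abs().sort_values(ascending=False).index)
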