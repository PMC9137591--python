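"""Published group-mean relative abundances (%) used as worked examples.

These are the printed phylum- and genus-level group-mean tables from the
broiler-chicken study this pipeline re-implements: per-taxon mean percent
abundance in each (sampling place, body-weight group) cell, the printed
place margins ("Mean (SP)") and body-weight margins ("Mean (BW)"). They are
inputs for the margin-recomputation checks: in the balanced design every
margin must be the arithmetic mean of its printed cells up to the printed
rounding (two decimals, so +/- 0.01).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

PLACE_ORDER = ("JC", "JM", "CC")
GROUP_ORDER = ("LBW", "HBW")


def _load(name: str):
    with resources.files("gutlinks.data").joinpath(name).open() as fh:
        raw = pd.read_csv(fh, sep="\t")
    cell_rows = raw[raw["row"].isin(GROUP_ORDER)]
    cells = {}
    for _, r in cell_rows.iterrows():
        for place in PLACE_ORDER:
            cells[(place, r["row"])] = cells.get((place, r["row"]), {})
            cells[(place, r["row"])][r["taxon"]] = float(r[place])
    taxa = list(dict.fromkeys(raw["taxon"]))
    frame = pd.DataFrame(
        {key: pd.Series(val) for key, val in cells.items()}
    ).loc[taxa]
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["place", "bw_group"])
    printed_bw = cell_rows.pivot(index="taxon", columns="row", values="printed_mean_bw")
    printed_bw = printed_bw.loc[taxa, list(GROUP_ORDER)].astype(float)
    sp_rows = raw[raw["row"] == "Mean(SP)"].set_index("taxon")
    printed_sp = sp_rows.loc[taxa, list(PLACE_ORDER)].astype(float)
    return frame, printed_sp, printed_bw


def phylum_table():
    """(cells, printed Mean(SP), printed Mean(BW)) of the phylum-level table."""
    return _load("phylum_group_means.tsv")


def genus_table():
    """(cells, printed Mean(SP), printed Mean(BW)) of the genus-level table."""
    return _load("genus_group_means.tsv")


DOMINANT_JC_PHYLA = ("Firmicutes", "Proteobacteria", "Cyanobacteria", "Actinobacteria")
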