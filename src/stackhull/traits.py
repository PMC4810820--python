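"""Ecological trait table for extant macroperforate planktonic foraminifera.

Fifteen species with three categorical traits each: symbiont type, habitat
depth and geographical (latitudinal) range. These feed the Jaccard-distance
ecological clustering in :mod:`stackhull.comparative`.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["foram_traits", "TRAIT_COLUMNS"]

TRAIT_COLUMNS = ("symbiont", "depth", "range")

_TABLE = [
    ("Globigerina bulloides", "none", "mixed layer", "mid"),
    ("Globigerinella siphonifera", "chrysophytes", "mixed layer/thermocline", "low-mid"),
    ("Globigerinoides conglobatus", "dinoflagellates", "mixed layer", "low"),
    ("Globigerinoides ruber", "dinoflagellates", "mixed layer", "low"),
    ("Globoconella inflata", "chrysophytes", "thermocline", "low-high"),
    ("Globorotalia tumida", "none", "thermocline/sub-thermocline", "low"),
    ("Hirsutella hirsuta", "none", "thermocline/sub-thermocline", "low-mid"),
    ("Menardella menardii", "chrysophytes", "thermocline", "low"),
    ("Neogloboquadrina dutertrei", "chrysophytes", "mixed layer/thermocline", "low"),
    ("Neogloboquadrina pachyderma", "none", "mixed layer/thermocline", "low-high"),
    ("Pulleniatina obliquiloculata", "chrysophytes", "mixed layer/thermocline", "low"),
    ("Sphaeroidinella dehiscens", "dinoflagellates", "thermocline", "low"),
    ("Trilobatus sacculifer", "dinoflagellates", "mixed layer", "low"),
    ("Truncorotalia crassaformis", "none", "sub-thermocline", "low-mid"),
    ("Truncorotalia truncatulinoides", "none", "sub-thermocline", "low"),
]


def foram_traits() -> pd.DataFrame:
    """Species-by-trait table, species names as the index.

    Levels: symbiont in {none, chrysophytes, dinoflagellates}; depth in
    {mixed layer, mixed layer/thermocline, thermocline,
    thermocline/sub-thermocline, sub-thermocline}; range in
    {low, low-mid, mid, low-high} latitudes.
    """
    df = pd.DataFrame(_TABLE, columns=("species",) + TRAIT_COLUMNS)
    return df.set_index("species")
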