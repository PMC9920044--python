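"""Packaged reference tables from the source maize DH study.

Three small plain-text fixtures ship with the package:

* ``qtl_table.tsv`` — the 42 lateral-angle QTL records (trait, peak
  position in cM and Mb, LOD, 1.5-LOD support interval bounds, percent
  variance explained, signed additive effect in degrees), including the
  study's curated "overlapping QTLs" annotation column;
* ``map_profile.tsv`` — the per-chromosome linkage-map profile (marker
  counts, mean/max adjacent gaps, genetic length);
* ``cob_color.json`` — the red:white cob counts (141:170) of the
  single-gene Mendelian validation trait.

These serve as worked-example inputs for the overlap and summary
operations and as ground truth for the packaged consistency checks.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

EXPECTED_QTL_ROWS = 42
EXPECTED_TRAIT_COUNTS = {"LA1": 12, "LA2": 8, "LA3": 9, "FLA": 6, "TBA": 7}

_NUMERIC_COLS = ["peak_cm", "peak_mb", "lod", "left_cm", "right_cm",
                 "left_mb", "right_mb", "pve", "add"]


def _data_path(name: str):
    return resources.files("dhqtl").joinpath("data").joinpath(name)


def load_table2(validate: bool = True) -> pd.DataFrame:
    """Load the packaged 42-QTL summary table.

    Columns: ``qtl, overlaps, trait, chrom, peak_marker, peak_cm,
    peak_mb, lod, left_cm, right_cm, left_mb, right_mb, pve, add``.
    ``overlaps`` is a comma-separated list of QTL names of other traits
    whose confidence regions the study reported as overlapping.
    """
    with _data_path("qtl_table.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"overlaps": str})
    df["overlaps"] = df["overlaps"].fillna("")
    if validate:
        if len(df) != EXPECTED_QTL_ROWS:
            raise ValueError(f"fixture must have {EXPECTED_QTL_ROWS} rows, "
                             f"got {len(df)}")
        counts = df["trait"].value_counts().to_dict()
        if counts != EXPECTED_TRAIT_COUNTS:
            raise ValueError(f"per-trait row counts {counts} != "
                             f"{EXPECTED_TRAIT_COUNTS}")
        for col in _NUMERIC_COLS:
            if not pd.api.types.is_numeric_dtype(df[col]):
                raise ValueError(f"column {col} must be numeric")
        bad = df[(df["left_cm"] > df["peak_cm"]) | (df["peak_cm"] > df["right_cm"])]
        if len(bad):
            raise ValueError(f"support interval must bracket peak: {bad['qtl'].tolist()}")
    return df


def load_map_profile() -> pd.DataFrame:
    """Per-chromosome linkage-map profile (10 rows, no totals row)."""
    with _data_path("map_profile.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    if len(df) != 10:
        raise ValueError("map profile must have 10 chromosomes")
    return df


def load_cob_counts() -> tuple[int, int]:
    """The (red, white) cob-color counts of the Mendelian check trait."""
    with _data_path("cob_color.json").open() as fh:
        payload = json.load(fh)
    return payload["classes"]["red"], payload["classes"]["white"]
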