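"""Bundled fixtures: the FPR pyrrolidine bis-diketopiperazine library and a
three-site toy library.

The FPR dataset is a four-site combinatorial series (alphabet sizes
5 x 8 x 9 x 17, M = 6120 definable analogues) of 106 codified compounds with
binding affinities against the two formylpeptide receptors FPR1 and FPR2.
For each property the 32 lowest-Ki compounds carry an interest flag; the
flags are stored as published, not re-derived from the transformed pK
values, and serve as the ground truth labels throughout.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .library import (
    LabeledLibrary,
    LibrarySpec,
    SiteSpec,
    enumerate_full_library,
    parse_labeled_library,
    parse_library_spec,
)

__all__ = ["load_toy_spec", "load_fpr", "make_toy_labeled", "make_fixtures", "FPRData"]


def _data_path(name: str):
    return importlib.resources.files("ssir.data").joinpath(name)


def load_toy_spec() -> LibrarySpec:
    """The 2 x 3 x 4 three-site toy library (M = 24 analogues)."""
    return LibrarySpec(
        (
            SiteSpec("R1", ("A", "B")),
            SiteSpec("R2", ("A", "B", "C")),
            SiteSpec("R3", ("A", "B", "C", "D")),
        )
    )


@dataclass
class FPRData:
    """The bundled FPR dataset: spec, raw table and per-property libraries."""

    spec: LibrarySpec
    frame: pd.DataFrame
    fpr1: LabeledLibrary
    fpr2: LabeledLibrary


def load_fpr() -> FPRData:
    """Load the 106-compound FPR1/FPR2 dataset and its four-site library."""
    with importlib.resources.as_file(_data_path("fpr_sites.tsv")) as p:
        spec = parse_library_spec(p, sep="\t")
    with importlib.resources.as_file(_data_path("fpr_compounds.tsv")) as p:
        frame = pd.read_csv(p, sep="\t")
        fpr1 = parse_labeled_library(
            frame.astype(str), spec, code_col="code", flag_col="fpr1_interest"
        )
        fpr2 = parse_labeled_library(
            frame.astype(str), spec, code_col="code", flag_col="fpr2_interest"
        )
    return FPRData(spec=spec, frame=frame, fpr1=fpr1, fpr2=fpr2)


def make_toy_labeled(seed: int = 0, a: int = 15, b: int = 5) -> LabeledLibrary:
    """Synthetic labeled sublibrary of the toy space (default a=15, b=5).

    The toy scenario fixes only the sublibrary sizes, not which analogues are
    known or of interest, so this generator samples them: *a* codes drawn
    without replacement from the 24-analogue toy library and *b* interest
    flags placed preferentially on analogues carrying residue A at site 2,
    so that site-2 rules are genuinely informative rather than noise.
    Deterministic for a given seed.
    """
    spec = load_toy_spec()
    rng = np.random.default_rng(seed)
    full = list(enumerate_full_library(spec))
    if not 0 < b < a <= len(full):
        raise ValueError("need 0 < b < a <= M")
    codes = [full[i] for i in sorted(rng.choice(len(full), size=a, replace=False))]
    weights = np.array([3.0 if c[1] == "A" else 1.0 for c in codes])
    flagged = rng.choice(a, size=b, replace=False, p=weights / weights.sum())
    interest = np.zeros(a, dtype=bool)
    interest[flagged] = True
    return LabeledLibrary(spec=spec, codes=codes, interest=interest)


def make_fixtures() -> dict:
    """All bundled fixtures keyed by name: toy spec, FPR spec and datasets."""
    fpr = load_fpr()
    return {
        "toy_spec": load_toy_spec(),
        "fpr_spec": fpr.spec,
        "fpr": fpr,
        "fpr1": fpr.fpr1,
        "fpr2": fpr.fpr2,
    }
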