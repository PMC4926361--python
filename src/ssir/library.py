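"""Codified combinatorial libraries of analogue series.

A combinatorial analogue series shares a scaffold with ``n`` substitution
sites; site ``i`` accepts one of ``m_i`` residues, each denoted by a symbolic
token.  The full library therefore contains ``M = prod(m_i)`` analogues, each
identified by its code -- the ordered list of residue tokens, e.g. ``CBDD``.
This module holds the library containers (:class:`LibrarySpec`,
:class:`LabeledLibrary`), the delimited-text readers/writers, full-library
enumeration and the dichotomization of continuous property values into
interest / non-interest flags.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SiteSpec",
    "LibrarySpec",
    "LabeledLibrary",
    "parse_library_spec",
    "write_library_spec",
    "parse_labeled_library",
    "write_labeled_library",
    "dichotomize",
    "enumerate_full_library",
]

#: An analogue code: one residue token per site.
AnalogueCode = tuple[str, ...]


@dataclass(frozen=True)
class SiteSpec:
    """One substitution site: its name and ordered residue alphabet."""

    name: str
    residues: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.residues) == 0:
            raise ValueError(f"site {self.name!r} has an empty residue alphabet")
        if len(set(self.residues)) != len(self.residues):
            raise ValueError(f"site {self.name!r} has duplicate residue symbols")
        if any(not r for r in self.residues):
            raise ValueError(f"site {self.name!r} has an empty residue token")

    @property
    def m(self) -> int:
        """Alphabet size of the site."""
        return len(self.residues)

    def index_of(self, residue: str) -> int:
        try:
            return self.residues.index(residue)
        except ValueError:
            raise KeyError(
                f"residue {residue!r} is not in site {self.name!r} alphabet {self.residues}"
            ) from None


@dataclass(frozen=True)
class LibrarySpec:
    """Ordered substitution sites defining a combinatorial library.

    The same token may appear in several sites; it stands for an independent
    codified entity at each position.  Sites with a single residue carry no
    information and are never constrained by rules, but they remain part of
    the codification.
    """

    sites: tuple[SiteSpec, ...]

    def __post_init__(self) -> None:
        if len(self.sites) < 2:
            raise ValueError(
                "a combinatorial library needs at least two substitution sites"
            )

    @property
    def n(self) -> int:
        """Number of substitution sites."""
        return len(self.sites)

    @property
    def m(self) -> tuple[int, ...]:
        """Per-site alphabet sizes ``(m_1, ..., m_n)``."""
        return tuple(s.m for s in self.sites)

    @property
    def M(self) -> int:
        """Total number of analogues definable in the library."""
        return math.prod(self.m)

    @property
    def constrained_sites(self) -> tuple[int, ...]:
        """0-based indices of sites with more than one residue."""
        return tuple(i for i, s in enumerate(self.sites) if s.m > 1)

    # -- code handling -----------------------------------------------------

    def parse_code(self, code: str | Sequence[str], sep: str | None = None) -> AnalogueCode:
        """Parse a compound code into a validated token tuple.

        With ``sep=None`` a string is split one character per site (the
        single-letter convention); otherwise it is split on ``sep``.  An
        already-tokenized sequence is validated as-is.
        """
        if isinstance(code, str):
            tokens = tuple(code.split(sep)) if sep else tuple(code)
        else:
            tokens = tuple(code)
        return self.validate_code(tokens)

    def validate_code(self, tokens: Sequence[str]) -> AnalogueCode:
        tokens = tuple(tokens)
        if len(tokens) != self.n:
            raise ValueError(
                f"code {tokens} has {len(tokens)} tokens, expected {self.n}"
            )
        for tok, site in zip(tokens, self.sites):
            if tok not in site.residues:
                raise KeyError(
                    f"residue {tok!r} is not in site {site.name!r} alphabet"
                )
        return tokens

    def format_code(self, code: AnalogueCode, sep: str = "") -> str:
        return sep.join(code)

    def encode(self, codes: Iterable[AnalogueCode]) -> np.ndarray:
        """Map codes to an ``(n_codes, n)`` array of residue indices."""
        lut = [
            {r: j for j, r in enumerate(site.residues)} for site in self.sites
        ]
        return np.array(
            [[lut[i][tok] for i, tok in enumerate(c)] for c in codes],
            dtype=np.int16,
        ).reshape(-1, self.n)

    def decode(self, idx: np.ndarray) -> list[AnalogueCode]:
        return [
            tuple(self.sites[i].residues[j] for i, j in enumerate(row))
            for row in np.asarray(idx, dtype=int)
        ]


def enumerate_full_library(spec: LibrarySpec) -> Iterator[AnalogueCode]:
    """Yield all ``M`` analogue codes of the library.

    Codes come in lexicographic order of site-alphabet indices (the Cartesian
    product ``R_1 x R_2 x ... x R_n`` with the last site varying fastest),
    deterministically.
    """
    yield from itertools.product(*(s.residues for s in spec.sites))


@dataclass
class LabeledLibrary:
    """The known sublibrary: ``a`` codified analogues, ``b`` flagged of interest.

    Parameters
    ----------
    spec : LibrarySpec
    codes : list of analogue codes, unique, valid under *spec*.
    interest : parallel boolean flags; True marks an analogue of interest.
    values : optional mapping of property name -> per-code real values.
    """

    spec: LibrarySpec
    codes: list[AnalogueCode]
    interest: np.ndarray
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codes = [self.spec.validate_code(c) for c in self.codes]
        self.interest = np.asarray(self.interest, dtype=bool)
        if len(self.codes) != self.interest.shape[0]:
            raise ValueError("codes and interest flags have different lengths")
        if len(set(self.codes)) != len(self.codes):
            seen: set[AnalogueCode] = set()
            dup = next(c for c in self.codes if c in seen or seen.add(c))
            raise ValueError(f"duplicate analogue code {''.join(dup)}")
        b = int(self.interest.sum())
        if b == 0 or b == len(self.codes):
            raise ValueError(
                f"need both classes present: a={len(self.codes)}, b={b}"
            )
        for name, v in self.values.items():
            arr = np.asarray(v, dtype=float)
            if arr.shape[0] != self.a:
                raise ValueError(f"property {name!r} length mismatch")
            self.values[name] = arr

    @property
    def a(self) -> int:
        """Number of known analogues."""
        return len(self.codes)

    @property
    def b(self) -> int:
        """Number of analogues flagged of interest."""
        return int(self.interest.sum())

    def encoded(self) -> np.ndarray:
        return self.spec.encode(self.codes)

    def subset(self, keep: Sequence[int]) -> "LabeledLibrary":
        """Sublibrary restricted to the given row positions (ITS refits)."""
        keep = list(keep)
        return LabeledLibrary(
            spec=self.spec,
            codes=[self.codes[i] for i in keep],
            interest=self.interest[keep],
            values={k: v[keep] for k, v in self.values.items()},
        )

    def relabel(self, interest: np.ndarray) -> "LabeledLibrary":
        return LabeledLibrary(self.spec, list(self.codes), interest, dict(self.values))


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

def _read_table(source, sep: str | None) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source
    if sep is None:
        sep = "\t" if str(source).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(source, sep=sep, dtype=str)


def parse_library_spec(source, sep: str | None = None) -> LibrarySpec:
    """Read a library spec table: one column per site, header = site names.

    Rows list the residue tokens of each site; blank cells mark unused
    alphabet slots for the shorter sites.
    """
    df = _read_table(source, sep)
    if df.shape[1] < 2:
        raise ValueError("library spec needs at least two site columns")
    sites = []
    for col in df.columns:
        residues = tuple(x.strip() for x in df[col].dropna() if str(x).strip())
        sites.append(SiteSpec(name=str(col), residues=residues))
    return LibrarySpec(tuple(sites))


def write_library_spec(spec: LibrarySpec, path, sep: str = "\t") -> None:
    width = max(s.m for s in spec.sites)
    cols = {
        s.name: list(s.residues) + [""] * (width - s.m) for s in spec.sites
    }
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)


def dichotomize(
    values: Sequence[float],
    mode: str = "threshold",
    parameter: float | int | None = None,
    direction: str = "low",
) -> np.ndarray:
    """Turn continuous property values into binary interest flags.

    Parameters
    ----------
    mode : {"threshold", "lowest_count", "lowest_fraction"}
        ``threshold`` flags values at or beyond *parameter* (inclusive);
        ``lowest_count`` flags exactly the *parameter* best-ranked values;
        ``lowest_fraction`` flags ``round(parameter * a)`` of them.
    direction : {"low", "high"}
        Whether low values are of interest (e.g. binding constants in nM)
        or high ones (e.g. pIC50).

    Boundary ties under count-based modes are resolved by stable input
    order and reported through a warning, so the requested count is exact.
    """
    v = np.asarray(values, dtype=float)
    a = v.shape[0]
    if direction not in ("low", "high"):
        raise ValueError("direction must be 'low' or 'high'")
    if mode == "threshold":
        if parameter is None:
            raise ValueError("threshold mode needs a cutoff parameter")
        return v <= parameter if direction == "low" else v >= parameter
    if mode == "lowest_fraction":
        if parameter is None or not 0 < parameter < 1:
            raise ValueError("lowest_fraction needs a parameter in (0, 1)")
        k = int(round(parameter * a))
    elif mode == "lowest_count":
        k = int(parameter) if parameter is not None else -1
    else:
        raise ValueError(f"unknown dichotomization mode {mode!r}")
    if not 0 < k < a:
        raise ValueError(f"count k={k} must satisfy 0 < k < a={a}")
    key = v if direction == "low" else -v
    order = np.argsort(key, kind="stable")
    flags = np.zeros(a, dtype=bool)
    flags[order[:k]] = True
    if key[order[k - 1]] == key[order[k]]:
        warnings.warn(
            f"boundary tie at rank {k}: equal values split by input order",
            stacklevel=2,
        )
    return flags


def parse_labeled_library(
    source,
    spec: LibrarySpec,
    code_col: str = "code",
    flag_col: str | None = None,
    property_col: str | None = None,
    label_mode: str = "flag",
    label_parameter: float | None = None,
    direction: str = "low",
    sep: str | None = None,
    token_sep: str | None = None,
) -> LabeledLibrary:
    """Read a codified compound table into a :class:`LabeledLibrary`.

    ``label_mode="flag"`` takes binary flags from *flag_col* (truthy markers:
    1/true/yes/``*``); the other modes dichotomize *property_col* via
    :func:`dichotomize`.  Codes are single-character-per-site strings unless
    *token_sep* is given.
    """
    df = _read_table(source, sep)
    if code_col not in df.columns:
        raise ValueError(f"column {code_col!r} not found in {list(df.columns)}")
    codes = [spec.parse_code(c, sep=token_sep) for c in df[code_col]]
    values: dict[str, np.ndarray] = {}
    for col in df.columns:
        if col in (code_col, flag_col):
            continue
        try:
            values[col] = df[col].astype(float).to_numpy()
        except (TypeError, ValueError):
            continue
    if label_mode == "flag":
        if flag_col is None:
            raise ValueError("label_mode='flag' needs flag_col")
        raw = df[flag_col].fillna("")
        truthy = {"1", "1.0", "true", "yes", "y", "*"}
        interest = raw.astype(str).str.strip().str.lower().isin(truthy).to_numpy()
    else:
        if property_col is None:
            raise ValueError(f"label_mode={label_mode!r} needs property_col")
        interest = dichotomize(
            df[property_col].astype(float).to_numpy(),
            mode=label_mode,
            parameter=label_parameter,
            direction=direction,
        )
    return LabeledLibrary(spec=spec, codes=codes, interest=interest, values=values)


def write_labeled_library(lib: LabeledLibrary, path, sep: str = "\t") -> None:
    df = pd.DataFrame({"code": [lib.spec.format_code(c) for c in lib.codes]})
    for name, v in lib.values.items():
        df[name] = v
    df["interest"] = lib.interest.astype(int)
    df.to_csv(path, sep=sep, index=False)
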