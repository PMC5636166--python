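"""Cross structure and design matrices for chromosome substitution strain panels.

A chromosome substitution strain (CSS) carries one donor-strain chromosome on
an otherwise host-strain background.  Crossing a maternal CSS with a paternal
CSS yields F1 animals heterozygous for up to two donor chromosomes; the full
panel of control, single and double crosses supports estimation of per-
chromosome main effects and pairwise inter-chromosomal interactions against
the host (B6) reference.

The design matrix built here uses treatment (reference) coding against the
control cross: one indicator per maternal substitution, one per paternal
substitution, and one product column per maternal x paternal pair observed in
the data.  Both the trait pipeline and the expression pipeline consume it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CrossLabel",
    "DesignMatrix",
    "RankDeficientDesignError",
    "enumerate_crosses",
    "build_design_matrix",
    "remove_small_cells",
]

# default panel: maternal donors on chromosomes 3/6/14/17, paternal on 4/5/8/10
MATERNAL_PANEL = ("3", "6", "14", "17")
PATERNAL_PANEL = ("4", "5", "8", "10")


def _chrom_key(c: str) -> tuple:
    """Sort chromosomes numerically when possible, then lexically ('X' last)."""
    try:
        return (0, int(c), "")
    except (TypeError, ValueError):
        return (1, 0, str(c))


def _norm(c) -> str | None:
    """Normalize a chromosome id to a string, mapping missing values to None."""
    if c is None:
        return None
    if isinstance(c, float) and np.isnan(c):
        return None
    s = str(c).strip()
    if s == "" or s.lower() in {"none", "nan", "na"}:
        return None
    # "4.0" from numeric CSV columns -> "4"
    if s.endswith(".0") and s[:-2].isdigit():
        s = s[:-2]
    return s


@dataclass(frozen=True)
class CrossLabel:
    """One of the cross types in a CSS panel.

    ``maternal_sub``/``paternal_sub`` hold the substituted chromosome id
    (string) or ``None``; ``CrossLabel(None, None)`` is the control host
    strain cross.
    """

    maternal_sub: str | None
    paternal_sub: str | None

    def __post_init__(self):
        object.__setattr__(self, "maternal_sub", _norm(self.maternal_sub))
        object.__setattr__(self, "paternal_sub", _norm(self.paternal_sub))

    @property
    def n_substitutions(self) -> int:
        return (self.maternal_sub is not None) + (self.paternal_sub is not None)

    @property
    def is_control(self) -> bool:
        return self.n_substitutions == 0

    @property
    def chromosomes(self) -> frozenset:
        return frozenset(
            c for c in (self.maternal_sub, self.paternal_sub) if c is not None
        )

    def __str__(self) -> str:
        m = self.maternal_sub or "B6"
        p = self.paternal_sub or "B6"
        return f"({m}x{p})"


class RankDeficientDesignError(ValueError):
    """Raised when the requested design matrix is not full column rank."""


def enumerate_crosses(
    maternal_panel: Iterable = MATERNAL_PANEL,
    paternal_panel: Iterable = PATERNAL_PANEL,
    exclusions: Iterable[CrossLabel] = (),
) -> list[CrossLabel]:
    """Enumerate control, single and double cross types for a CSS panel.

    Parameters
    ----------
    maternal_panel, paternal_panel
        Chromosome ids substituted on the maternal / paternal side.  The two
        panels must be non-empty and disjoint (each chromosome appears on one
        parental side only).
    exclusions
        Cross types bred but not analyzable (e.g. poor breeders); exclusions
        not in the enumerated set are ignored with a warning.

    Returns
    -------
    list of CrossLabel, ordered: control, maternal singles, paternal singles,
    then double crosses (maternal-major, panel sort order).
    """
    mat = sorted({_norm(c) for c in maternal_panel} - {None}, key=_chrom_key)
    pat = sorted({_norm(c) for c in paternal_panel} - {None}, key=_chrom_key)
    if not mat or not pat:
        raise ValueError("both panels must be non-empty")
    if set(mat) & set(pat):
        raise ValueError(f"panels must be disjoint, overlap: {set(mat) & set(pat)}")

    crosses = [CrossLabel(None, None)]
    crosses += [CrossLabel(m, None) for m in mat]
    crosses += [CrossLabel(None, p) for p in pat]
    crosses += [CrossLabel(m, p) for m in mat for p in pat]

    excl = set(exclusions)
    unknown = excl - set(crosses)
    if unknown:
        warnings.warn(f"exclusions not in enumerated set, ignored: {sorted(map(str, unknown))}")
    return [c for c in crosses if c not in excl]


@dataclass
class DesignMatrix:
    """Indicator design for a set of observations.

    Attributes
    ----------
    X : pandas.DataFrame
        One row per observation; columns ``Intercept``, ``mat<chrom>``,
        ``pat<chrom>`` and ``int<chrom_m>:<chrom_p>`` with 0/1 entries.
    term_classes : dict
        Column -> one of ``intercept``, ``main_maternal``, ``main_paternal``,
        ``interaction``.
    crosses : pandas.Series
        The CrossLabel of each row (index aligned with ``X``).
    """

    X: pd.DataFrame
    term_classes: dict = field(default_factory=dict)
    crosses: pd.Series | None = None

    @property
    def main_terms(self) -> list[str]:
        return [c for c, k in self.term_classes.items() if k.startswith("main")]

    @property
    def interaction_terms(self) -> list[str]:
        return [c for c, k in self.term_classes.items() if k == "interaction"]

    def terms_of_class(self, term_class: str) -> list[str]:
        if term_class == "main":
            return self.main_terms
        if term_class == "interaction":
            return self.interaction_terms
        return [c for c, k in self.term_classes.items() if k == term_class]

    def drop_interactions(self) -> "DesignMatrix":
        """The average-effect design: same rows, interaction columns removed."""
        keep = [c for c in self.X.columns if self.term_classes[c] != "interaction"]
        return DesignMatrix(
            X=self.X[keep].copy(),
            term_classes={c: self.term_classes[c] for c in keep},
            crosses=self.crosses,
        )


def crosses_from_frame(records: pd.DataFrame) -> pd.Series:
    """Extract a CrossLabel per row from maternal_sub / paternal_sub columns."""
    return pd.Series(
        [
            CrossLabel(m, p)
            for m, p in zip(records["maternal_sub"], records["paternal_sub"])
        ],
        index=records.index,
    )


def build_design_matrix(
    records: pd.DataFrame,
    include_interactions: bool = True,
    maternal_panel: Iterable | None = None,
    paternal_panel: Iterable | None = None,
) -> DesignMatrix:
    """Build the reference-coded design matrix for a phenotype table or sample sheet.

    ``records`` needs ``maternal_sub`` and ``paternal_sub`` columns (empty /
    NaN meaning no substitution).  Indicator columns are emitted for every
    substitution level present in the data (or the full panel if given);
    interaction columns only for maternal x paternal pairs actually observed.
    A full-rank check is performed: a design where an interaction column
    duplicates a main column (a single-CSS cell is empty) raises
    :class:`RankDeficientDesignError` naming the offending cell.
    """
    crosses = crosses_from_frame(records)
    obs_mat = {c.maternal_sub for c in crosses if c.maternal_sub is not None}
    obs_pat = {c.paternal_sub for c in crosses if c.paternal_sub is not None}
    if maternal_panel is not None:
        allowed = {_norm(m) for m in maternal_panel} - {None}
        bad = obs_mat - allowed
        if bad:
            raise ValueError(f"maternal substitutions outside panel: {sorted(bad)}")
    if paternal_panel is not None:
        allowed = {_norm(p) for p in paternal_panel} - {None}
        bad = obs_pat - allowed
        if bad:
            raise ValueError(f"paternal substitutions outside panel: {sorted(bad)}")
    # columns only for observed levels, so single-sided tables stay full rank
    mats = sorted(obs_mat, key=_chrom_key)
    pats = sorted(obs_pat, key=_chrom_key)

    n = len(records)
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(n)}
    classes: dict[str, str] = {"Intercept": "intercept"}
    mat_arr = np.array([c.maternal_sub for c in crosses], dtype=object)
    pat_arr = np.array([c.paternal_sub for c in crosses], dtype=object)
    for m in mats:
        cols[f"mat{m}"] = (mat_arr == m).astype(float)
        classes[f"mat{m}"] = "main_maternal"
    for p in pats:
        cols[f"pat{p}"] = (pat_arr == p).astype(float)
        classes[f"pat{p}"] = "main_paternal"
    if include_interactions:
        observed_pairs = sorted(
            {
                (c.maternal_sub, c.paternal_sub)
                for c in crosses
                if c.n_substitutions == 2
            },
            key=lambda mp: (_chrom_key(mp[0]), _chrom_key(mp[1])),
        )
        for m, p in observed_pairs:
            cols[f"int{m}:{p}"] = cols[f"mat{m}"] * cols[f"pat{p}"]
            classes[f"int{m}:{p}"] = "interaction"

    X = pd.DataFrame(cols, index=records.index)
    dm = DesignMatrix(X=X, term_classes=classes, crosses=crosses)
    _check_full_rank(dm)
    return dm


def _check_full_rank(dm: DesignMatrix) -> None:
    Xv = dm.X.to_numpy()
    rank = np.linalg.matrix_rank(Xv)
    if rank == Xv.shape[1]:
        return
    # name the offending cell: an interaction column linearly dependent on
    # earlier columns usually means a supporting single-CSS cell is empty
    for j, col in enumerate(dm.X.columns):
        sub = np.linalg.matrix_rank(Xv[:, : j + 1])
        if sub < j + 1:
            raise RankDeficientDesignError(
                f"design matrix is rank deficient at column '{col}' "
                f"(rank {rank} < {Xv.shape[1]} columns); a supporting cross "
                "cell is empty or collinear"
            )
    raise RankDeficientDesignError("design matrix is rank deficient")


def remove_small_cells(
    records: pd.DataFrame,
    min_cell: int = 5,
    by_sex: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop animals belonging to cross(xsex) cells with fewer than ``min_cell``.

    Returns the retained table and a log frame of removed cells
    (cross, sex, n).  Removing a double-CSS cell drops the corresponding
    interaction column when the design is rebuilt (pairs no longer observed),
    while main-effect columns survive through the remaining cells.
    """
    crosses = crosses_from_frame(records)
    keys = [crosses]
    names = ["cross"]
    if by_sex and "sex" in records.columns:
        keys.append(records["sex"])
        names.append("sex")
    sizes = records.groupby(keys, sort=False).size()
    small = sizes[sizes < min_cell]
    if small.empty:
        return records, pd.DataFrame(columns=[*names, "n"])
    removed = small.rename("n").reset_index()
    removed.columns = [*names, "n"]
    mask = pd.Series(True, index=records.index)
    for _, row in removed.iterrows():
        sel = crosses == row["cross"]
        if "sex" in removed.columns:
            sel &= records["sex"] == row["sex"]
        mask &= ~sel
    return records[mask].copy(), removed
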