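"""Sire-dam pedigrees and the numerator relationship matrix A.

A is the matrix of expected additive-genetic relationships implied by the
pedigree: founders have diagonal 1, an inbred individual has diagonal
``1 + F`` with F the inbreeding coefficient, and the breeding-value
covariance of the additive random-regression coefficients is ``A (x) D``.
Its inverse enters Henderson's mixed model equations, and is built directly
from the pedigree by Henderson's rules with the Quaas correction for
inbreeding rather than by dense inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["UNKNOWN", "Pedigree", "RelationshipMatrix", "sort_pedigree", "build_A", "build_A_inverse"]

UNKNOWN = "0"


class PedigreeError(ValueError):
    pass


def _norm_id(x) -> str:
    """Normalize an ID field; '', '0', NA -> UNKNOWN."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return UNKNOWN
    s = str(x).strip()
    return s if s not in ("", "0", "NA", "nan") else UNKNOWN


@dataclass
class Pedigree:
    """Ordered (individual, sire, dam) records; UNKNOWN marks missing parents."""

    records: list[tuple[str, str, str]] = field(default_factory=list)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        """Build from a 3-column table (id, sire, dam); 0/empty = unknown.

        Individuals appearing only as parents are appended as founders.
        """
        recs = [
            (_norm_id(i), _norm_id(s), _norm_id(d))
            for i, s, d in df.iloc[:, :3].itertuples(index=False)
        ]
        ids = {r[0] for r in recs}
        extras = []
        for _, s, d in recs:
            for p in (s, d):
                if p != UNKNOWN and p not in ids:
                    ids.add(p)
                    extras.append((p, UNKNOWN, UNKNOWN))
        return cls(records=extras + recs)

    @classmethod
    def read_csv(cls, path) -> "Pedigree":
        df = pd.read_csv(path, dtype=str, sep=None, engine="python")
        return cls.from_frame(df)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["id", "sire", "dam"])

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    def parents(self) -> dict[str, tuple[str, str]]:
        return {i: (s, d) for i, s, d in self.records}

    def __len__(self) -> int:
        return len(self.records)


def sort_pedigree(ped: Pedigree) -> Pedigree:
    """Topologically sort so every known parent precedes its offspring.

    Stable: ties keep input order.  Raises ``PedigreeError`` naming an
    individual on a cycle if the ancestry graph is cyclic.
    """
    par = ped.parents()
    order: list[str] = []
    state: dict[str, int] = {}  # 0 visiting, 1 done

    for root in par:
        if root in state:
            continue
        stack = [(root, iter([p for p in par[root] if p in par]))]
        state[root] = 0
        while stack:
            node, it = stack[-1]
            advanced = False
            for p in it:
                if state.get(p) == 0:
                    raise PedigreeError(f"pedigree cycle involving individual {p!r}")
                if p not in state:
                    state[p] = 0
                    stack.append((p, iter([q for q in par[p] if q in par])))
                    advanced = True
                    break
            if not advanced:
                state[node] = 1
                order.append(node)
                stack.pop()

    pos = {i: k for k, i in enumerate(order)}
    recs = sorted(ped.records, key=lambda r: pos[r[0]])
    return Pedigree(records=recs)


@dataclass
class RelationshipMatrix:
    """Numerator relationship matrix with its individual ordering."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("relationship matrix shape does not match id list")
        self._index = {i: k for k, i in enumerate(self.ids)}

    def submatrix(self, ids) -> np.ndarray:
        """A restricted to (and ordered by) the given individuals."""
        try:
            idx = [self._index[i] for i in ids]
        except KeyError as e:
            raise KeyError(f"individual {e.args[0]!r} not in relationship matrix") from None
        return self.values[np.ix_(idx, idx)]

    def inbreeding(self) -> np.ndarray:
        return np.diag(self.values) - 1.0


def build_A(ped: Pedigree) -> RelationshipMatrix:
    """Tabular-method numerator relationship matrix.

    a_ii = 1 + 0.5 a_{sire,dam}; a_ij = 0.5 (a_{j,sire} + a_{j,dam}) for j
    before i; unknown parents contribute 0.
    """
    ped = sort_pedigree(ped)
    ids = ped.ids
    idx = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    for i, (ind, sire, dam) in enumerate(ped.records):
        s = idx.get(sire, -1)
        d = idx.get(dam, -1)
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
    return RelationshipMatrix(ids=ids, values=A)


def build_A_inverse(ped: Pedigree) -> RelationshipMatrix:
    """A^-1 by Henderson's rules with the Quaas inbreeding correction.

    For individual i with parents s, d the contribution is
    ``alpha_i = 1 / m_i`` added to the (i, s, d) block with weights
    (1, -0.5, -0.5) outer-producted, where the Mendelian-sampling variance
    is ``m_i = 1 - 0.25 (a_ss + a_dd)`` over the known parents (so it
    depends only on parental inbreeding); parent diagonals come from the
    tabular A, handling inbreeding exactly.
    """
    ped = sort_pedigree(ped)
    ids = ped.ids
    idx = {i: k for k, i in enumerate(ids)}
    diag = np.diag(build_A(ped).values)  # a_ii = 1 + F_i
    n = len(ids)
    Ainv = np.zeros((n, n))
    for i, (ind, sire, dam) in enumerate(ped.records):
        s = idx.get(sire, -1)
        d = idx.get(dam, -1)
        var_ms = 1.0 - 0.25 * ((diag[s] if s >= 0 else 0.0) + (diag[d] if d >= 0 else 0.0))
        # always > 0 for a valid pedigree (parental F < 1)
        alpha = 1.0 / var_ms
        members = [(i, 1.0)] + [(p, -0.5) for p in (s, d) if p >= 0]
        for a, wa in members:
            for b, wb in members:
                Ainv[a, b] += alpha * wa * wb
    return RelationshipMatrix(ids=ids, values=Ainv)
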