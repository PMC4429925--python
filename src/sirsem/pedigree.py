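"""Sire-maternal-grandsire pedigrees and the numerator relationship matrix.

In a sire model the genetic effect is attached to bulls, and relationships
among bulls are tracked through each bull's sire and maternal grandsire (MGS).
The numerator relationship matrix A follows the standard recursion

    a_kj = 0.5 * a(j, sire_k) + 0.25 * a(j, mgs_k)        (j before k)
    a_kk = 1 + 0.25 * a(sire_k, mgs_k)

with missing ancestors contributing nothing (unknown parents are treated as
unrelated founders).  The inverse is assembled directly from the same
recursion: writing u_k = 0.5 u_s + 0.25 u_g + phi_k with
var(phi_k) = a_kk - (0.25 a_ss + 0.0625 a_gg + 0.25 a_sg), each individual
contributes the outer product of (1, -0.5, -0.25) / var(phi_k) over the
(k, sire, MGS) positions.  The two constructions are exact inverses of each
other for any pedigree the recursion admits, including inbred bulls.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InputError, NumericalError, PedigreeError

#: Tokens interpreted as "ancestor unknown" in pedigree files.
UNKNOWN_TOKENS = {"", "0", "NA", "na", ".", "none", "None"}

UNKNOWN = -1  # internal index code for an unknown ancestor


@dataclass(frozen=True)
class SireMgsPedigree:
    """A topologically ordered sire-MGS pedigree.

    ``ids[i]`` is the i-th individual; ``sire[i]`` / ``mgs[i]`` are indices
    into ``ids`` (or ``-1`` for unknown) and always precede ``i``.
    """

    ids: tuple[str, ...]
    sire: np.ndarray
    mgs: np.ndarray

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, ids) -> np.ndarray:
        """Map external id strings to pedigree row indices."""
        lookup = {v: i for i, v in enumerate(self.ids)}
        try:
            return np.array([lookup[str(v)] for v in ids], dtype=int)
        except KeyError as exc:
            raise InputError(f"id {exc.args[0]!r} not in pedigree") from None

    def to_frame(self) -> pd.DataFrame:
        sire = [self.ids[s] if s >= 0 else "0" for s in self.sire]
        mgs = [self.ids[g] if g >= 0 else "0" for g in self.mgs]
        return pd.DataFrame({"id": self.ids, "sire": sire, "mgs": mgs})


@dataclass(frozen=True)
class RelationshipMatrix:
    """Numerator relationship matrix A and its inverse over pedigree rows."""

    pedigree: SireMgsPedigree
    A: np.ndarray
    A_inv: np.ndarray

    def rows_for(self, ids) -> np.ndarray:
        """Row indices of A for external ids (e.g. the sire column of data)."""
        return self.pedigree.index_of(ids)


def make_pedigree(entries) -> SireMgsPedigree:
    """Build a validated pedigree from (id, sire, mgs) triples.

    Parents referenced but never listed are appended as unknown-parent
    founders.  Entries may arrive in any order; the result is topologically
    sorted so ancestors precede descendants.
    """
    ids: list[str] = []
    seen: set[str] = set()
    parents: dict[str, tuple[str | None, str | None]] = {}

    def norm(tok) -> str | None:
        tok = "" if tok is None else str(tok).strip()
        return None if tok in UNKNOWN_TOKENS else tok

    for row in entries:
        ind, s, g = (str(row[0]).strip(), norm(row[1]), norm(row[2]))
        if ind in UNKNOWN_TOKENS:
            raise InputError("individual id missing in pedigree row")
        if ind in seen:
            raise InputError(f"duplicate individual {ind!r} in pedigree")
        seen.add(ind)
        ids.append(ind)
        parents[ind] = (s, g)
    for ind in list(ids):
        for par in parents[ind]:
            if par is not None and par not in seen:
                seen.add(par)
                ids.append(par)
                parents[par] = (None, None)

    # Kahn topological sort over the ancestry DAG (stable w.r.t. input order).
    order: list[str] = []
    unresolved = dict(parents)
    placed: set[str] = set()
    while unresolved:
        batch = [
            ind
            for ind in ids
            if ind in unresolved
            and all(p is None or p in placed for p in unresolved[ind])
        ]
        if not batch:
            cyc = sorted(unresolved)[:6]
            raise PedigreeError(
                f"ancestry cycle in pedigree involving {cyc} "
                "(an individual is its own ancestor)"
            )
        for ind in batch:
            order.append(ind)
            placed.add(ind)
            del unresolved[ind]

    pos = {v: i for i, v in enumerate(order)}
    sire = np.array(
        [pos[parents[v][0]] if parents[v][0] is not None else UNKNOWN for v in order]
    )
    mgs = np.array(
        [pos[parents[v][1]] if parents[v][1] is not None else UNKNOWN for v in order]
    )
    return SireMgsPedigree(ids=tuple(order), sire=sire, mgs=mgs)


def read_pedigree(path: str | Path, sep: str | None = None) -> SireMgsPedigree:
    """Read a 3-column delimited pedigree file (id, sire, MGS).

    ``"0"`` or an empty field marks an unknown ancestor.  The delimiter is
    sniffed unless given.  A header row is detected by the canonical column
    names and skipped.
    """
    df = pd.read_csv(path, sep=sep, engine="python", header=None, dtype=str,
                     comment="#", skip_blank_lines=True)
    if df.shape[1] < 3:
        raise InputError(
            f"pedigree file {path} must have three columns (id, sire, mgs)"
        )
    df = df.iloc[:, :3].fillna("0")
    first = [str(v).lower() for v in df.iloc[0]]
    if first[0] in {"id", "individual", "animal"}:
        df = df.iloc[1:]
    return make_pedigree(df.itertuples(index=False, name=None))


def write_pedigree(ped: SireMgsPedigree, path: str | Path) -> None:
    ped.to_frame().to_csv(path, sep="\t", index=False, header=False)


def build_A_sire_mgs(ped: SireMgsPedigree) -> RelationshipMatrix:
    """Construct A (tabular method) and A^-1 (direct assembly) for a pedigree.

    Returns a :class:`RelationshipMatrix`; raises :class:`NumericalError`
    if the result is not positive definite, which signals an inconsistent
    pedigree.
    """
    A = tabular_A(ped)
    A_inv = direct_A_inverse(ped)
    try:
        np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        raise NumericalError("relationship matrix is not positive definite") from None
    resid = np.abs(A @ A_inv - np.eye(ped.n)).max() if ped.n else 0.0
    if resid > 1e-8:
        raise NumericalError(
            f"A and its assembled inverse disagree (max |A A^-1 - I| = {resid:.2e})"
        )
    return RelationshipMatrix(pedigree=ped, A=A, A_inv=A_inv)


def tabular_A(ped: SireMgsPedigree) -> np.ndarray:
    """Numerator relationship matrix by the tabular (recursive) method."""
    n = ped.n
    A = np.zeros((n, n))
    for k in range(n):
        s, g = ped.sire[k], ped.mgs[k]
        row = np.zeros(k)
        if s != UNKNOWN:
            row += 0.5 * A[s, :k]
        if g != UNKNOWN:
            row += 0.25 * A[g, :k]
        A[k, :k] = row
        A[:k, k] = row
        asg = A[s, g] if (s != UNKNOWN and g != UNKNOWN) else 0.0
        A[k, k] = 1.0 + 0.25 * asg
    return A


def direct_A_inverse(ped: SireMgsPedigree) -> np.ndarray:
    """Assemble A^-1 directly from per-individual recursion contributions.

    Uses exact per-individual residual variances computed from the tabular
    relationships of the parents, so inbred ancestors are handled without the
    non-inbred shortcut constants.
    """
    n = ped.n
    A = tabular_A(ped)  # needed for exact residual variances
    Ainv = np.zeros((n, n))
    for k in range(n):
        s, g = ped.sire[k], ped.mgs[k]
        a_ss = A[s, s] if s != UNKNOWN else 0.0
        a_gg = A[g, g] if g != UNKNOWN else 0.0
        a_sg = A[s, g] if (s != UNKNOWN and g != UNKNOWN) else 0.0
        v = A[k, k] - (0.25 * a_ss + 0.0625 * a_gg + 0.25 * a_sg)
        if v <= 0:
            raise NumericalError(
                f"non-positive residual variance for {ped.ids[k]!r}; "
                "pedigree is inconsistent"
            )
        idx = [k]
        w = [1.0]
        if s != UNKNOWN:
            idx.append(s)
            w.append(-0.5)
        if g != UNKNOWN:
            idx.append(g)
            w.append(-0.25)
        w = np.array(w)
        Ainv[np.ix_(idx, idx)] += np.outer(w, w) / v
    return Ainv
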