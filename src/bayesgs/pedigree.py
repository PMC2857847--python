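"""Pedigree container and the additive genetic relationship matrix A.

The polygenic term of the whole-genome regression model assumes
``u ~ N(0, A * sigma2_u)`` where A is the numerator relationship matrix
derived from the pedigree.  A is built with the recursive tabular method,
which accounts for inbreeding exactly: the diagonal is 1 + F_i where F_i
is the animal's inbreeding coefficient.
"""

from __future__ import annotations

import numpy as np

UNKNOWN = -1


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees."""


class Pedigree:
    """Ordered pedigree records.

    Parameters
    ----------
    sire, dam : arrays of int
        0-based index of each animal's parents within this pedigree,
        ``UNKNOWN`` (-1) for base-population animals.  Parents must appear
        before their offspring (topological order).
    generation : array of int, optional
        Discrete generation number per animal (0 = founders).
    phenotyped : boolean array, optional
        Mask of animals carrying phenotypic records.  Defaults to all True.
    family : array of int, optional
        Full-sib family label for the validation generation, -1 elsewhere.
    """

    def __init__(self, sire, dam, generation=None, phenotyped=None, family=None):
        self.sire = np.asarray(sire, dtype=np.int64)
        self.dam = np.asarray(dam, dtype=np.int64)
        if self.sire.shape != self.dam.shape:
            raise PedigreeError("sire and dam arrays must have equal length")
        n = self.n_animals
        self.generation = None if generation is None else np.asarray(generation, dtype=np.int64)
        self.phenotyped = (
            np.ones(n, dtype=bool) if phenotyped is None else np.asarray(phenotyped, dtype=bool)
        )
        self.family = None if family is None else np.asarray(family, dtype=np.int64)
        self.validate()

    @property
    def n_animals(self) -> int:
        return int(self.sire.shape[0])

    @property
    def ids(self) -> np.ndarray:
        """1-based animal identifiers used in file output."""
        return np.arange(1, self.n_animals + 1)

    def is_founder(self) -> np.ndarray:
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    def validate(self) -> None:
        """Check topological order: every known parent precedes its offspring.

        Because parent indices are strictly smaller than offspring indices,
        the pedigree is automatically acyclic (no animal can be its own
        ancestor).
        """
        idx = np.arange(self.n_animals)
        for name, par in (("sire", self.sire), ("dam", self.dam)):
            known = par != UNKNOWN
            if np.any(par[known] < 0) or np.any(par[known] >= self.n_animals):
                raise PedigreeError(f"{name} index out of range")
            if np.any(par[known] >= idx[known]):
                raise PedigreeError(
                    f"pedigree not topologically sorted: a {name} does not precede "
                    "its offspring; sort parents before offspring and retry"
                )


def build_A(pedigree: Pedigree) -> np.ndarray:
    """Additive relationship matrix by the recursive tabular method.

    ``a_ii = 1 + 0.5 * a(sire_i, dam_i)`` and, for j < i,
    ``a_ij = 0.5 * (a(j, sire_i) + a(j, dam_i))`` with an unknown parent
    contributing zero.  Rows are filled in pedigree order, so the
    recursion only ever reads entries already computed.

    Returns
    -------
    ndarray
        Symmetric positive semidefinite n x n matrix; diagonal entries are
        1 + F_i >= 1.
    """
    pedigree.validate()
    n = pedigree.n_animals
    sire, dam = pedigree.sire, pedigree.dam
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s != UNKNOWN:
            row += A[s, :i]
        if d != UNKNOWN:
            row += A[d, :i]
        row *= 0.5
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s != UNKNOWN and d != UNKNOWN) else 0.0)
    return A


def write_A(A: np.ndarray, path, fmt: str = "%.6f") -> None:
    """Dense text dump of a relationship matrix, for debugging."""
    np.savetxt(path, A, fmt=fmt)


def write_pedigree(pedigree: Pedigree, path) -> None:
    """Write `animal_id sire_id dam_id` (1-based, 0 = unknown parent)."""
    ids = pedigree.ids
    with open(path, "w") as fh:
        fh.write("animal_id,sire_id,dam_id\n")
        for i in range(pedigree.n_animals):
            s = 0 if pedigree.sire[i] == UNKNOWN else pedigree.sire[i] + 1
            d = 0 if pedigree.dam[i] == UNKNOWN else pedigree.dam[i] + 1
            fh.write(f"{ids[i]},{s},{d}\n")


def read_pedigree(path) -> Pedigree:
    """Read the pedigree format written by :func:`write_pedigree`.

    Accepts comma- or whitespace-separated columns, with or without the
    header line.  Animal ids must be 1..n in file order; 0 marks an
    unknown parent.
    """
    sires, dams = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if lineno == 0 and not parts[0].lstrip("-").isdigit():
                continue  # header
            a, s, d = (int(x) for x in parts[:3])
            if a != len(sires) + 1:
                raise PedigreeError(f"animal ids must be consecutive 1..n, got {a}")
            sires.append(s - 1 if s > 0 else UNKNOWN)
            dams.append(d - 1 if d > 0 else UNKNOWN)
    return Pedigree(np.array(sires, dtype=np.int64), np.array(dams, dtype=np.int64))
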