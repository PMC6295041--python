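"""Pedigree relationships: the numerator relationship matrix A, inbreeding,
Henderson's sparse A-inverse, the genotyped-animal submatrix A22, and
effective population size from the per-generation rate of inbreeding.

Conventions
-----------
Animals are renumbered to dense internal ids 1..n with parents preceding
offspring; 0 denotes an unknown parent, which is treated as an unrelated,
non-inbred founder. Internally, arrays are 0-based with -1 for unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "Pedigree",
    "PedigreeError",
    "read_pedigree",
    "write_pedigree",
    "compute_inbreeding",
    "tabular_A",
    "build_A_inverse",
    "extract_A22",
    "ne_from_inbreeding",
]

# guard for dense tabular A (test/oracle scale only)
MAX_TABULAR_N = 5000


class PedigreeError(ValueError):
    """Invalid pedigree: cycles, dangling parent ids, or bad structure."""


@dataclass
class Pedigree:
    """Topologically sorted pedigree with dense internal ids.

    Attributes
    ----------
    sire, dam : int arrays of length n, 0-based internal parent indices,
        -1 for unknown.
    labels : original external ids, position i holds the label of internal
        animal i.
    generation : optional int array of year-class / generation labels
        (-1 when absent for an animal).
    """

    sire: np.ndarray
    dam: np.ndarray
    labels: np.ndarray
    generation: np.ndarray | None = None
    id_map: dict = field(default_factory=dict)  # external label -> internal index

    def __post_init__(self):
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self.labels = np.asarray(self.labels)
        if not self.id_map:
            self.id_map = {lab: i for i, lab in enumerate(self.labels)}
        n = len(self.sire)
        for name, par in (("sire", self.sire), ("dam", self.dam)):
            if np.any(par >= np.arange(n)):
                bad = int(np.nonzero(par >= np.arange(n))[0][0])
                raise PedigreeError(
                    f"{name} of animal {self.labels[bad]} does not precede it; "
                    "pedigree is not topologically sorted"
                )

    def __len__(self) -> int:
        return len(self.sire)

    @property
    def n(self) -> int:
        return len(self.sire)

    def internal(self, external_ids) -> np.ndarray:
        """Map external labels to 0-based internal indices."""
        try:
            return np.array([self.id_map[e] for e in external_ids], dtype=np.int64)
        except KeyError as err:
            raise PedigreeError(f"unknown animal id {err.args[0]}") from None

    def is_founder(self) -> np.ndarray:
        return (self.sire < 0) & (self.dam < 0)

    def families(self) -> dict:
        """Group non-founder animals into full-sib families keyed by
        (sire, dam) internal indices."""
        fams: dict = {}
        for i in range(self.n):
            s, d = int(self.sire[i]), int(self.dam[i])
            if s >= 0 or d >= 0:
                fams.setdefault((s, d), []).append(i)
        return fams

    def generations(self) -> np.ndarray:
        """Generation number per animal: the year-class label when supplied,
        otherwise the maximum ancestral depth (founders = 0)."""
        if self.generation is not None and np.all(self.generation >= 0):
            return self.generation.copy()
        depth = np.zeros(self.n, dtype=np.int64)
        for i in range(self.n):
            ds = depth[self.sire[i]] + 1 if self.sire[i] >= 0 else 0
            dd = depth[self.dam[i]] + 1 if self.dam[i] >= 0 else 0
            depth[i] = max(ds, dd)
        return depth


def _toposort_records(df: pd.DataFrame) -> Pedigree:
    ids = df["animal"].to_numpy()
    if len(set(ids)) != len(ids):
        dup = df["animal"][df["animal"].duplicated()].iloc[0]
        raise PedigreeError(f"duplicate animal id {dup}")
    known = set(ids)
    for col in ("sire", "dam"):
        bad = df.loc[(df[col] != 0) & ~df[col].isin(known), col]
        if len(bad):
            raise PedigreeError(
                f"unknown parent id {bad.iloc[0]} referenced but never defined"
            )

    pos = {a: i for i, a in enumerate(ids)}
    sire_raw = df["sire"].to_numpy()
    dam_raw = df["dam"].to_numpy()

    # Kahn topological sort, stable in input order
    n = len(ids)
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=np.int64)
    for i in range(n):
        for p in (sire_raw[i], dam_raw[i]):
            if p != 0:
                children[pos[p]].append(i)
                indeg[i] += 1
    order: list[int] = []
    queue = [i for i in range(n) if indeg[i] == 0]
    head = 0
    while head < len(queue):
        i = queue[head]
        head += 1
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(order) != n:
        offending = ids[int(np.nonzero(indeg > 0)[0][0])]
        raise PedigreeError(f"pedigree cycle detected involving animal {offending}")

    newpos = {ids[old]: new for new, old in enumerate(order)}
    sire = np.array(
        [newpos[sire_raw[old]] if sire_raw[old] != 0 else -1 for old in order]
    )
    dam = np.array(
        [newpos[dam_raw[old]] if dam_raw[old] != 0 else -1 for old in order]
    )
    labels = ids[order]
    gen = None
    if "year_class" in df.columns:
        gen = df["year_class"].to_numpy()[order].astype(np.int64)
    return Pedigree(sire=sire, dam=dam, labels=labels, generation=gen)


def read_pedigree(path) -> Pedigree:
    """Read a delimited pedigree file (animal, sire, dam[, year_class];
    0 = unknown parent), renumber, and topologically sort it.

    Raises :class:`PedigreeError` on cycles or dangling parent ids.
    """
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    if isinstance(df.iloc[0, 0], str) and not str(df.iloc[0, 0]).lstrip("-").isdigit():
        df = df.iloc[1:].reset_index(drop=True)  # header row present
    if df.shape[1] not in (3, 4):
        raise PedigreeError(f"expected 3 or 4 columns, got {df.shape[1]}")
    cols = ["animal", "sire", "dam"] + (["year_class"] if df.shape[1] == 4 else [])
    df.columns = cols
    df = df.astype(np.int64)
    if (df["animal"] < 1).any():
        raise PedigreeError("animal ids must be >= 1")
    return _toposort_records(df)


def from_arrays(sire, dam, labels=None, generation=None) -> Pedigree:
    """Build a Pedigree from already-sorted 0-based parent arrays."""
    sire = np.asarray(sire, dtype=np.int64)
    if labels is None:
        labels = np.arange(1, len(sire) + 1)
    gen = None if generation is None else np.asarray(generation, dtype=np.int64)
    return Pedigree(sire=sire, dam=np.asarray(dam, dtype=np.int64),
                    labels=np.asarray(labels), generation=gen)


def write_pedigree(ped: Pedigree, path) -> None:
    """Write the renumbered pedigree (internal 1-based ids) plus the
    original-id map as CSV."""
    df = pd.DataFrame(
        {
            "animal": np.arange(1, ped.n + 1),
            "sire": ped.sire + 1,
            "dam": ped.dam + 1,
            "original_id": ped.labels,
        }
    )
    if ped.generation is not None:
        df["year_class"] = ped.generation
    df.to_csv(path, index=False)


def compute_inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F for every animal, Meuwissen & Luo style.

    Works animal by animal on the ancestral path, avoiding the full
    tabular A; unknown parents contribute no inbreeding.
    """
    n = ped.n
    sire, dam = ped.sire, ped.dam
    F = np.zeros(n)
    # d_i: Mendelian sampling variance given parental inbreeding; filled as
    # we go since parents precede offspring.
    d = np.empty(n)
    L = np.zeros(n)

    for i in range(n):
        s, dm = sire[i], dam[i]
        d[i] = 0.5 - 0.25 * ((F[s] if s >= 0 else -1.0) + (F[dm] if dm >= 0 else -1.0))
        if s < 0 or dm < 0:
            F[i] = 0.0
            continue
        # trace ancestors of i in decreasing index order, accumulating
        # path coefficients L; F_i = sum_j L_j^2 d_j - 1
        fi = -1.0
        L[i] = 1.0
        active = {i}
        while active:
            j = max(active)
            active.remove(j)
            r = 0.5 * L[j]
            for p in (sire[j], dam[j]):
                if p >= 0:
                    if p in active:
                        L[p] += r
                    else:
                        L[p] = r
                        active.add(p)
            fi += L[j] * L[j] * d[j]
            L[j] = 0.0
        F[i] = fi
    return F


def tabular_A(ped: Pedigree, max_n: int = MAX_TABULAR_N) -> np.ndarray:
    """Dense numerator relationship matrix by the recursive tabular method.

    a_ii = 1 + 0.5*a(sire,dam); a_ij = 0.5*(a(j,sire_i) + a(j,dam_i)) for
    j < i. Intended as an oracle and for small subsets; refuses n > max_n.
    """
    n = ped.n
    if n > max_n:
        raise PedigreeError(
            f"dense tabular A refused for n={n} > {max_n}; "
            "use extract_A22 or build_A_inverse"
        )
    A = np.zeros((n, n))
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A


def build_A_inverse(ped: Pedigree, F: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse inverse of the numerator relationship matrix by Henderson's
    rules, accounting for inbreeding.

    The Mendelian-sampling variance for animal i is
    d_i = 0.5 - 0.25*(F_s + F_d) with both parents known,
    d_i = 0.75 - 0.25*F_p with one parent known, and 1 with none.
    """
    if F is None:
        F = compute_inbreeding(ped)
    n = ped.n
    sire, dam = ped.sire, ped.dam
    rows, cols, vals = [], [], []
    for i in range(n):
        s, d = int(sire[i]), int(dam[i])
        fs = F[s] if s >= 0 else -1.0
        fd = F[d] if d >= 0 else -1.0
        di = 0.5 - 0.25 * (fs + fd)
        alpha = 1.0 / di
        rows.append(i); cols.append(i); vals.append(alpha)
        for p in (s, d):
            if p >= 0:
                rows += [i, p]; cols += [p, i]; vals += [-alpha / 2, -alpha / 2]
        for p in (s, d):
            if p >= 0:
                rows.append(p); cols.append(p); vals.append(alpha / 4)
        if s >= 0 and d >= 0:
            rows += [s, d]; cols += [d, s]; vals += [alpha / 4, alpha / 4]
    A_inv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return A_inv


def _ancestor_closure(ped: Pedigree, idx: np.ndarray) -> np.ndarray:
    """All ancestors of idx (inclusive), as a sorted internal-index array."""
    keep = np.zeros(ped.n, dtype=bool)
    keep[idx] = True
    for i in range(ped.n - 1, -1, -1):
        if keep[i]:
            if ped.sire[i] >= 0:
                keep[ped.sire[i]] = True
            if ped.dam[i] >= 0:
                keep[ped.dam[i]] = True
    return np.nonzero(keep)[0]


def extract_A22(ped: Pedigree, genotyped_ids) -> np.ndarray:
    """Pedigree relationship submatrix over the genotyped animals.

    Computed on the ancestral closure of the genotyped set only, so the
    full dense A over all n animals is never formed.

    Parameters
    ----------
    genotyped_ids : external animal labels of the genotyped subset.
    """
    g_int = ped.internal(genotyped_ids)
    anc = _ancestor_closure(ped, g_int)
    remap = -np.ones(ped.n, dtype=np.int64)
    remap[anc] = np.arange(len(anc))
    sub_sire = np.where(ped.sire[anc] >= 0, remap[np.maximum(ped.sire[anc], 0)], -1)
    sub_dam = np.where(ped.dam[anc] >= 0, remap[np.maximum(ped.dam[anc], 0)], -1)
    sub = Pedigree(sire=sub_sire, dam=sub_dam, labels=ped.labels[anc])
    A_sub = tabular_A(sub, max_n=max(MAX_TABULAR_N, len(anc)))
    pos = remap[g_int]
    return A_sub[np.ix_(pos, pos)]


def ne_from_inbreeding(mean_F_by_generation, mode: str = "mean"):
    """Effective population size from the rate of inbreeding.

    dF between consecutive generations is (F_n - F_{n-1}) / (1 - F_{n-1});
    Ne = 1 / (2*dF). With more than two generations, `mode="mean"`
    averages dF over consecutive pairs, `mode="last"` uses the final pair.

    Returns (Ne, dF) where Ne is NaN (flagged missing) when dF <= 0.
    """
    F = np.asarray(mean_F_by_generation, dtype=float)
    if len(F) < 2:
        raise ValueError("need mean F for at least two generations")
    if np.any(F[:-1] >= 1.0):
        raise ValueError("F must be < 1 in all but the last generation")
    dF_seq = (F[1:] - F[:-1]) / (1.0 - F[:-1])
    if mode == "mean":
        dF = float(np.mean(dF_seq))
    elif mode == "last":
        dF = float(dF_seq[-1])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if dF <= 0:
        return float("nan"), dF
    return 1.0 / (2.0 * dF), dF
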