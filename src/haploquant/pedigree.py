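"""Pedigrees and haplodiploid relatedness.

Under haplodiploidy females are diploid and males haploid: a father
transmits his entire (single) genome to every daughter, so full sisters
share all paternal alleles and are related by r = 0.75 instead of the
diplodiploid 0.5.  Sons develop from unfertilized eggs and carry a single
maternally derived genome.  The same transmission rules govern an
X/Z sex chromosome, which is why the haplodiploid relationship matrix
coincides with a sex-chromosome ("S") relationship matrix.

This module builds validated, topologically sorted pedigrees from CSV,
computes the haplodiploid kinship matrix by recursion, scales it to the
additive (numerator) relationship matrix over females, and provides a
gene-dropping Monte-Carlo estimator used as an independent oracle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Individual",
    "Pedigree",
    "PedigreeError",
    "RelatednessMatrix",
    "read_pedigree",
    "kinship",
    "additive_matrix",
    "gene_drop_relatedness",
]

FEMALE = "female"
MALE = "male"

_SEX_ALIASES = {
    "f": FEMALE,
    "female": FEMALE,
    "m": MALE,
    "male": MALE,
}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, sex conflicts, dupes)."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``dam``/``sire`` are ids of the (diploid female) mother and (haploid
    male) father, or ``None`` for founders of unknown ancestry.  ``nest``
    and ``cohort`` carry the colony and birth-season labels used by the
    maternal- and year-effect terms downstream.
    """

    id: str
    sex: str
    dam: str | None = None
    sire: str | None = None
    nest: str | None = None
    cohort: str | None = None

    def __post_init__(self) -> None:
        sex = _SEX_ALIASES.get(str(self.sex).strip().lower())
        if sex is None:
            raise PedigreeError(f"individual {self.id!r}: unknown sex {self.sex!r}")
        object.__setattr__(self, "sex", sex)

    @property
    def is_founder(self) -> bool:
        return self.dam is None and self.sire is None


class Pedigree:
    """Topologically ordered collection of individuals.

    Parents always precede their offspring in ``self.individuals``;
    every referenced parent exists (parents absent from the input are
    materialized as implicit founders of the appropriate sex).
    """

    def __init__(self, individuals: Iterable[Individual]):
        members = list(individuals)
        ids = [ind.id for ind in members]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dupes = sorted({i for i in ids if i in seen or seen.add(i)})
            raise PedigreeError(f"duplicate individual ids: {dupes}")

        by_id = {ind.id: ind for ind in members}

        # Materialize referenced-but-absent parents as implicit founders.
        implicit: list[Individual] = []
        for ind in members:
            if ind.dam is not None and ind.dam not in by_id:
                founder = Individual(id=ind.dam, sex=FEMALE)
                by_id[founder.id] = founder
                implicit.append(founder)
            if ind.sire is not None and ind.sire not in by_id:
                founder = Individual(id=ind.sire, sex=MALE)
                by_id[founder.id] = founder
                implicit.append(founder)
        members = implicit + members

        for ind in members:
            if ind.dam is not None and by_id[ind.dam].sex != FEMALE:
                raise PedigreeError(
                    f"individual {ind.id!r}: dam {ind.dam!r} is not female"
                )
            if ind.sire is not None and by_id[ind.sire].sex != MALE:
                raise PedigreeError(
                    f"individual {ind.id!r}: sire {ind.sire!r} is not male"
                )

        order = {ind.id: k for k, ind in enumerate(members)}
        graph = nx.DiGraph()
        graph.add_nodes_from(ind.id for ind in members)
        for ind in members:
            for parent in (ind.dam, ind.sire):
                if parent is not None:
                    graph.add_edge(parent, ind.id)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = [edge[0] for edge in nx.find_cycle(graph)]
            raise PedigreeError(f"parentage cycle involving ids: {cycle}")
        sorted_ids = list(
            nx.lexicographical_topological_sort(graph, key=order.__getitem__)
        )

        self.individuals: tuple[Individual, ...] = tuple(by_id[i] for i in sorted_ids)
        self.index: dict[str, int] = {i: k for k, i in enumerate(sorted_ids)}
        self.implicit_founders: tuple[str, ...] = tuple(f.id for f in implicit)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)

    def __getitem__(self, id_: str) -> Individual:
        return self.individuals[self.index[id_]]

    def __contains__(self, id_: str) -> bool:
        return id_ in self.index

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(ind.id for ind in self.individuals)

    @property
    def females(self) -> tuple[str, ...]:
        return tuple(ind.id for ind in self.individuals if ind.sex == FEMALE)

    def founders(self) -> tuple[str, ...]:
        return tuple(ind.id for ind in self.individuals if ind.is_founder)

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(dam_idx, sire_idx) arrays in pedigree order, -1 for missing."""
        dam = np.full(len(self), -1, dtype=np.int64)
        sire = np.full(len(self), -1, dtype=np.int64)
        for k, ind in enumerate(self.individuals):
            if ind.dam is not None:
                dam[k] = self.index[ind.dam]
            if ind.sire is not None:
                sire[k] = self.index[ind.sire]
        return dam, sire

    def nests(self) -> dict[str, list[str]]:
        """Map nest label -> member ids (pedigree order), skipping unlabelled."""
        out: dict[str, list[str]] = {}
        for ind in self.individuals:
            if ind.nest is not None:
                out.setdefault(ind.nest, []).append(ind.id)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(ind) for ind in self.individuals])

    def write_csv(self, path: str | Path) -> None:
        frame = self.to_frame()
        frame = frame[["id", "dam", "sire", "sex", "nest", "cohort"]]
        frame.to_csv(path, index=False)


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a pedigree CSV with columns id, dam, sire, sex, nest, cohort.

    Empty strings denote missing values; extra columns are ignored; row
    order need not be topological.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"pedigree file not found: {path}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"id", "dam", "sire", "sex"}
    missing = required - set(frame.columns)
    if missing:
        raise PedigreeError(f"pedigree CSV missing columns: {sorted(missing)}")
    return pedigree_from_frame(frame)


def pedigree_from_frame(frame: pd.DataFrame) -> Pedigree:
    def _opt(value) -> str | None:
        if value is None:
            return None
        value = str(value).strip()
        return value or None

    individuals = [
        Individual(
            id=str(row["id"]).strip(),
            sex=row["sex"],
            dam=_opt(row.get("dam")),
            sire=_opt(row.get("sire")),
            nest=_opt(row.get("nest")),
            cohort=_opt(row.get("cohort")),
        )
        for row in frame.to_dict("records")
    ]
    return Pedigree(individuals)


class RelatednessMatrix:
    """Symmetric relatedness matrix over a stated set of individuals.

    ``kind`` records the scale: ``"kinship"`` holds coefficients of
    kinship phi(i, j); ``"additive"`` and ``"gene_drop"`` hold the
    numerator relationship a(i, j) = 2 phi(i, j).
    """

    def __init__(
        self,
        ids: Sequence[str],
        values: np.ndarray,
        kind: str = "additive",
        stderr: np.ndarray | None = None,
    ):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(ids), len(ids)):
            raise ValueError("matrix shape does not match id list")
        self.ids = tuple(ids)
        self.values = values
        self.kind = kind
        self.stderr = stderr
        self._pos = {i: k for k, i in enumerate(self.ids)}
        self._eigen: tuple[np.ndarray, np.ndarray] | None = None

    def loc(self, i: str, j: str) -> float:
        return float(self.values[self._pos[i], self._pos[j]])

    def submatrix(self, ids: Sequence[str]) -> "RelatednessMatrix":
        idx = np.array([self._pos[i] for i in ids])
        return RelatednessMatrix(ids, self.values[np.ix_(idx, idx)], kind=self.kind)

    def eigen(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached (eigenvalues, eigenvectors) of the matrix (ascending)."""
        if self._eigen is None:
            d, u = np.linalg.eigh(self.values)
            self._eigen = (d, u)
        return self._eigen

    def min_eigenvalue(self) -> float:
        return float(self.eigen()[0][0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_long(self) -> pd.DataFrame:
        ii, jj = np.triu_indices(len(self.ids))
        return pd.DataFrame(
            {
                "id1": np.asarray(self.ids)[ii],
                "id2": np.asarray(self.ids)[jj],
                "a": self.values[ii, jj],
            }
        )

    def write_csv(self, path: str | Path, format: str = "wide") -> None:
        if format == "wide":
            self.to_frame().to_csv(path, index_label="id")
        elif format == "long":
            self.to_long().to_csv(path, index=False)
        else:
            raise ValueError(f"unknown matrix format {format!r}")


def kinship(ped: Pedigree) -> RelatednessMatrix:
    """Haplodiploid kinship matrix phi over all pedigree members.

    Recursion in pedigree (topological) order, with founders mutually
    unrelated:

    * phi(i, i) = (1 + F_i) / 2 for a female, F_i = phi(dam_i, sire_i);
      phi(i, i) = 1 for a (haploid) male;
    * female i, older j: phi(i, j) = phi(dam, j)/2 + phi(sire, j)/2;
    * male i, older j:   phi(i, j) = phi(dam, j);
    * a missing parent contributes 0 (unique unrelated founder).
    """
    n = len(ped)
    dam, sire = ped.parent_indices()
    female = np.array([ind.sex == FEMALE for ind in ped], dtype=bool)
    phi = np.zeros((n, n))
    for i in range(n):
        d, s = dam[i], sire[i]
        if female[i]:
            row = np.zeros(i)
            if d >= 0:
                row += 0.5 * phi[d, :i]
            if s >= 0:
                row += 0.5 * phi[s, :i]
            inbreeding = phi[d, s] if (d >= 0 and s >= 0) else 0.0
            phi[i, i] = 0.5 * (1.0 + inbreeding)
        else:
            row = phi[d, :i].copy() if d >= 0 else np.zeros(i)
            phi[i, i] = 1.0
        phi[i, :i] = row
        phi[:i, i] = row
    return RelatednessMatrix(ped.ids, phi, kind="kinship")


def additive_matrix(
    ped: Pedigree,
    subset: Sequence[str] | None = None,
    phi: RelatednessMatrix | None = None,
) -> RelatednessMatrix:
    """Additive (numerator) relationship matrix a = 2 phi over females.

    The matrix is restricted to ``subset`` (default: every female) but the
    kinship recursion always runs through the full pedigree, so known
    multigenerational links are respected.  Diagonal entries equal
    1 + F_i.  Males are deliberately unsupported: additive scaling across
    ploidy levels is convention-dependent and all phenotyped wasps are
    female.
    """
    if subset is None:
        subset = ped.females
    males = [i for i in subset if ped[i].sex != FEMALE]
    if males:
        raise ValueError(f"additive_matrix subset must be all-female; males: {males}")
    if phi is None:
        phi = kinship(ped)
    sub = phi.submatrix(subset)
    return RelatednessMatrix(subset, 2.0 * sub.values, kind="additive")


def gene_drop_relatedness(
    ped: Pedigree,
    reps: int,
    seed: int,
    chunk: int = 512,
) -> RelatednessMatrix:
    """Monte-Carlo relatedness by gene dropping; the oracle for the algebra.

    Each replicate labels founder chromosomes uniquely (two per female,
    one per male) and transmits them: a daughter gets one random maternal
    allele plus the single paternal allele; a son gets one random
    maternal allele.  phi(i, j) is estimated as the probability that
    random allele picks from i and j are identical by descent; the
    returned matrix holds 2 * phi_hat with a per-entry Monte-Carlo
    standard error in ``stderr``.

    Males are stored as homozygous for their single allele, which makes
    the pair statistic (mean equality over the four slot pairs) valid for
    every sex combination, including phi(male, male self) = 1.
    """
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    n = len(ped)
    dam, sire = ped.parent_indices()
    female = np.array([ind.sex == FEMALE for ind in ped], dtype=bool)
    rng = np.random.default_rng(seed)

    # Constant founder labels; a missing parent side gets its own unique
    # label, equivalent to an unobserved unrelated founder.
    labels = np.zeros((n, 2), dtype=np.int64)
    counter = 0
    for i in range(n):
        if female[i]:
            labels[i] = (counter, counter + 1)
            counter += 2
        else:  # haploid male: one allele, stored homozygous
            labels[i] = (counter, counter)
            counter += 1

    sum1 = np.zeros((n, n))
    sum2 = np.zeros((n, n))
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        alleles = np.broadcast_to(labels, (m, n, 2)).copy()
        for i in range(n):
            d, s = dam[i], sire[i]
            if d < 0 and s < 0:
                continue
            if d >= 0:
                pick = rng.integers(0, 2, size=m)
                maternal = alleles[np.arange(m), d, pick]
            else:
                maternal = alleles[:, i, 0]
            if female[i]:
                paternal = alleles[:, s, 0] if s >= 0 else alleles[:, i, 1]
                alleles[:, i, 0] = maternal
                alleles[:, i, 1] = paternal
            else:
                alleles[:, i, 0] = maternal
                alleles[:, i, 1] = maternal
        # Per-replicate pair statistic: mean IBD indicator over the 4
        # ordered allele-slot pairs; its expectation is phi.
        stat = np.zeros((m, n, n))
        for s1 in (0, 1):
            for s2 in (0, 1):
                stat += alleles[:, :, None, s1] == alleles[:, None, :, s2]
        stat *= 0.25
        sum1 += stat.sum(axis=0)
        sum2 += (stat * stat).sum(axis=0)
        done += m

    phi_hat = sum1 / reps
    var = np.maximum(sum2 / reps - phi_hat**2, 0.0) / reps
    return RelatednessMatrix(
        ped.ids, 2.0 * phi_hat, kind="gene_drop", stderr=2.0 * np.sqrt(var)
    )
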