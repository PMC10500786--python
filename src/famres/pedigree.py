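"""Pedigree handling: PED ingestion, validation, kinship, relative-pair labels.

A pedigree is a forest of families indexed by family id.  Individuals are
keyed by ``(fid, iid)``; parent links point at individuals in the same
family, with ``"0"`` (or ``None``) standing for an unknown, unrelated
founder.  Kinship coefficients are computed family-by-family with the
classical recursion over a topological (parents-before-children) order, so
the overall kinship matrix is block-diagonal and cross-family entries are
implicitly zero.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

MISSING_PARENT = "0"

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"

_SEX_CODES = {"1": MALE, "2": FEMALE, "0": UNKNOWN}
_SEX_TO_CODE = {MALE: "1", FEMALE: "2", UNKNOWN: "0"}


class PedigreeError(ValueError):
    """Base class for pedigree problems."""


class PedParseError(PedigreeError):
    """Malformed PED row."""


class PedValidationError(PedigreeError):
    """Structurally invalid pedigree (missing parents, sex conflicts...)."""


class PedCycleError(PedigreeError):
    """An individual is its own ancestor."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``father``/``mother`` are iids within the same family, or ``None`` for
    an unknown unrelated founder.
    """

    fid: str
    iid: str
    father: str | None = None
    mother: str | None = None
    sex: str = UNKNOWN
    birth_year: int | None = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.fid, self.iid)

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


@dataclass(frozen=True)
class RelativePair:
    """A labelled within-family dyad.

    For asymmetric relations the order is (senior role, junior role):
    parent before offspring, grandparent before grandchild, aunt/uncle
    before niece/nephew, brother before sister.
    """

    fid: str
    iid_a: str
    iid_b: str
    relation: str
    degree: str
    flagged: bool = False  # True when unknown sex forced a sex-agnostic label


#: Relations whose two roles are exchangeable (double-entry ICC applies).
SYMMETRIC_RELATIONS = frozenset(
    {"spouse", "sister-sister", "brother-brother", "half-sibling", "cousin", "sibling"}
)

#: Full taxonomy in precedence order (closest label wins for a dyad).
RELATION_PRECEDENCE = (
    "spouse",
    "parent-offspring",
    "full-sibling",
    "half-sibling",
    "grandparent",
    "avuncular",
    "cousin",
)

_DEGREE = {
    "spouse": "spouse",
    "father-son": "first",
    "father-daughter": "first",
    "mother-son": "first",
    "mother-daughter": "first",
    "parent-offspring": "first",
    "sister-sister": "first",
    "brother-brother": "first",
    "brother-sister": "first",
    "sibling": "first",
    "half-sibling": "second",
    "grandparent": "second",
    "avuncular": "second",
    "cousin": "second",
}


def relation_degree(relation: str) -> str:
    return _DEGREE[relation]


class Pedigree:
    """A validated set of families with parent links.

    Validation enforces: named parents exist in the same family, fathers
    are male and mothers female (unknown sex is inferred from the parental
    role), no individual is its own ancestor, and iids are unique within a
    family.
    """

    def __init__(self, individuals: Iterable[Individual]):
        self._members: dict[tuple[str, str], Individual] = {}
        self._families: dict[str, list[str]] = defaultdict(list)
        for ind in individuals:
            if ind.key in self._members:
                raise PedValidationError(
                    f"duplicate individual {ind.iid!r} in family {ind.fid!r}"
                )
            self._members[ind.key] = ind
            self._families[ind.fid].append(ind.iid)
        self._families = dict(self._families)
        self._infer_parent_sexes()
        self._validate()
        self._topo_cache: dict[str, list[str]] = {}

    # -- construction helpers -------------------------------------------------

    def _infer_parent_sexes(self) -> None:
        """Force father=male / mother=female; infer when sex is unknown."""
        forced: dict[tuple[str, str], str] = {}
        for ind in self._members.values():
            for parent_iid, want in ((ind.father, MALE), (ind.mother, FEMALE)):
                if parent_iid is None:
                    continue
                key = (ind.fid, parent_iid)
                parent = self._members.get(key)
                if parent is None:
                    raise PedValidationError(
                        f"parent {parent_iid!r} of {ind.iid!r} missing from "
                        f"family {ind.fid!r}"
                    )
                if parent.sex == UNKNOWN:
                    forced[key] = want
                elif parent.sex != want:
                    role = "father" if want == MALE else "mother"
                    raise PedValidationError(
                        f"{role} {parent_iid!r} of {ind.iid!r} in family "
                        f"{ind.fid!r} has sex {parent.sex!r}"
                    )
        for key, sex in forced.items():
            old = self._members[key]
            logger.info("inferring sex=%s for parental %s/%s", sex, *key)
            self._members[key] = Individual(
                old.fid, old.iid, old.father, old.mother, sex, old.birth_year
            )

    def _validate(self) -> None:
        for fid in self._families:
            graph = self._parent_graph(fid)
            if not nx.is_directed_acyclic_graph(graph):
                cycle = nx.find_cycle(graph)
                raise PedCycleError(
                    f"family {fid!r}: individual is its own ancestor "
                    f"(cycle through {cycle[0][0]!r})"
                )

    def _parent_graph(self, fid: str) -> nx.DiGraph:
        """Directed graph with an edge parent -> child."""
        graph = nx.DiGraph()
        graph.add_nodes_from(self._families[fid])
        for iid in self._families[fid]:
            ind = self._members[(fid, iid)]
            for parent in (ind.father, ind.mother):
                if parent is not None:
                    graph.add_edge(parent, iid)
        return graph

    # -- basic access ---------------------------------------------------------

    @property
    def family_ids(self) -> list[str]:
        return list(self._families)

    def family_members(self, fid: str) -> list[Individual]:
        """Members of one family, in input row order."""
        return [self._members[(fid, iid)] for iid in self._families[fid]]

    def __len__(self) -> int:
        return len(self._members)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self._members.values())

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._members

    def get(self, fid: str, iid: str) -> Individual:
        return self._members[(fid, iid)]

    def founders(self, fid: str) -> list[Individual]:
        return [m for m in self.family_members(fid) if m.is_founder]

    def topological_order(self, fid: str) -> list[str]:
        """iids of one family with every parent before its children."""
        if fid not in self._topo_cache:
            graph = self._parent_graph(fid)
            # deterministic tie-break: input row order
            order = {iid: k for k, iid in enumerate(self._families[fid])}
            self._topo_cache[fid] = list(
                nx.lexicographical_topological_sort(graph, key=order.__getitem__)
            )
        return self._topo_cache[fid]

    def to_ped(self, path) -> None:
        """Write LINKAGE/PLINK-style pre-MAKEPED PED text."""
        with open(path, "w") as fh:
            for ind in self._members.values():
                fh.write(
                    "\t".join(
                        (
                            ind.fid,
                            ind.iid,
                            ind.father or MISSING_PARENT,
                            ind.mother or MISSING_PARENT,
                            _SEX_TO_CODE[ind.sex],
                        )
                    )
                    + "\n"
                )


def read_ped(path, dialect: str = "pre-makeped") -> Pedigree:
    """Read a LINKAGE/PLINK-style PED file.

    Expects >=5 whitespace-delimited columns: FID IID FATHER MOTHER SEX,
    with missing parents coded ``"0"`` and sex coded 1=male, 2=female,
    0=unknown.  Any further columns (phenotypes) are ignored.
    """
    if dialect != "pre-makeped":
        raise ValueError(f"unknown PED dialect {dialect!r}")
    individuals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 5:
                raise PedParseError(
                    f"{path}:{lineno}: expected >=5 columns, got {len(fields)}"
                )
            fid, iid, father, mother, sex_code = fields[:5]
            if sex_code not in _SEX_CODES:
                raise PedParseError(
                    f"{path}:{lineno}: bad sex code {sex_code!r} (want 0/1/2)"
                )
            if iid == MISSING_PARENT:
                raise PedParseError(f"{path}:{lineno}: iid must not be '0'")
            individuals.append(
                Individual(
                    fid=fid,
                    iid=iid,
                    father=None if father == MISSING_PARENT else father,
                    mother=None if mother == MISSING_PARENT else mother,
                    sex=_SEX_CODES[sex_code],
                )
            )
    return Pedigree(individuals)


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------


class KinshipMatrix:
    """Block-diagonal kinship coefficients, one dense block per family.

    ``phi[i][j]`` is the probability that one allele drawn from i and one
    from j are identical by descent; the diagonal is 0.5*(1 + F_i) with
    F_i the inbreeding coefficient.  Cross-family coefficients are zero
    and never materialised.
    """

    def __init__(self, blocks: dict[str, tuple[list[str], np.ndarray]]):
        self._blocks = blocks

    @property
    def family_ids(self) -> list[str]:
        return list(self._blocks)

    def __contains__(self, fid: str) -> bool:
        return fid in self._blocks

    @property
    def ids(self) -> list[tuple[str, str]]:
        """All (fid, iid) keys in block order."""
        return [(fid, iid) for fid, (iids, _) in self._blocks.items() for iid in iids]

    def block(self, fid: str) -> tuple[list[str], np.ndarray]:
        """(iids, phi matrix) for one family."""
        return self._blocks[fid]

    def phi(self, fid_a: str, iid_a: str, fid_b: str, iid_b: str) -> float:
        if fid_a != fid_b:
            return 0.0
        iids, mat = self._blocks[fid_a]
        return float(mat[iids.index(iid_a), iids.index(iid_b)])

    def inbreeding(self, fid: str, iid: str) -> float:
        """F = 2*phi(i,i) - 1."""
        return 2.0 * self.phi(fid, iid, fid, iid) - 1.0

    def to_triplets(self, path) -> None:
        """Write the non-zero lower triangle as TSV (fid, iid_a, iid_b, phi)."""
        with open(path, "w") as fh:
            fh.write("fid\tiid_a\tiid_b\tphi\n")
            for fid, (iids, mat) in self._blocks.items():
                for i, iid_a in enumerate(iids):
                    for j in range(i + 1):
                        if mat[i, j] != 0.0:
                            fh.write(f"{fid}\t{iid_a}\t{iids[j]}\t{mat[i, j]:.10g}\n")


def kinship(ped: Pedigree) -> KinshipMatrix:
    """Kinship coefficients by the classical recursion.

    Founders: phi(i,i)=0.5 and phi(i,j)=0 for distinct founders.  For a
    non-founder i and any j that is not a descendant of i (guaranteed by
    processing a topological order),

        phi(i,j) = 0.5*(phi(father_i, j) + phi(mother_i, j))
        phi(i,i) = 0.5*(1 + phi(father_i, mother_i))

    A missing parent contributes 0 (unknown unrelated founder).
    """
    blocks: dict[str, tuple[list[str], np.ndarray]] = {}
    for fid in ped.family_ids:
        order = ped.topological_order(fid)
        index = {iid: k for k, iid in enumerate(order)}
        n = len(order)
        mat = np.zeros((n, n))
        for i, iid in enumerate(order):
            ind = ped.get(fid, iid)
            fa = index.get(ind.father) if ind.father is not None else None
            mo = index.get(ind.mother) if ind.mother is not None else None
            for j in range(i):
                val = 0.0
                if fa is not None:
                    val += 0.5 * mat[fa, j]
                if mo is not None:
                    val += 0.5 * mat[mo, j]
                mat[i, j] = mat[j, i] = val
            phi_fm = mat[fa, mo] if (fa is not None and mo is not None) else 0.0
            mat[i, i] = 0.5 * (1.0 + phi_fm)
        # restore input row order
        rows = ped.family_members(fid)
        perm = [index[m.iid] for m in rows]
        blocks[fid] = ([m.iid for m in rows], mat[np.ix_(perm, perm)])
    return KinshipMatrix(blocks)


# ---------------------------------------------------------------------------
# Relative-pair classification
# ---------------------------------------------------------------------------


def _full_sibs(a: Individual, b: Individual) -> bool:
    return (
        a.father is not None
        and a.mother is not None
        and a.father == b.father
        and a.mother == b.mother
    )


def _half_sibs(a: Individual, b: Individual) -> bool:
    """Exactly one shared *named* parent."""
    shared = 0
    if a.father is not None and a.father == b.father:
        shared += 1
    if a.mother is not None and a.mother == b.mother:
        shared += 1
    return shared == 1


def _parents(ind: Individual) -> list[str]:
    return [p for p in (ind.father, ind.mother) if p is not None]


def classify_pairs(
    ped: Pedigree, fids: Iterable[str] | None = None
) -> list[RelativePair]:
    """Label every within-family dyad that fits the relation taxonomy.

    Relations: spouse (male-female pair with >=1 shared offspring),
    father-son/father-daughter/mother-son/mother-daughter, the three
    full-sibling dyads, half-sibling, grandparent(-grandchild), avuncular
    (full sibling of a parent), and first cousin (a parent of each are
    full siblings).  When several hold the closest wins, in the order
    spouse > parent-offspring > full sibling > half sibling > grandparent
    > avuncular > cousin; the suppressed label is logged.  Dyads with an
    unknown-sex member that would need a sexed label fall into the
    sex-agnostic "parent-offspring"/"sibling" buckets with ``flagged=True``.
    Deeper links (e.g. great-grandparent) are left unlabelled.
    """
    out: list[RelativePair] = []
    for fid in fids if fids is not None else ped.family_ids:
        members = ped.family_members(fid)
        by_iid = {m.iid: m for m in members}
        children_of: dict[str, set[str]] = defaultdict(set)
        for m in members:
            for p in _parents(m):
                children_of[p].add(m.iid)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                labels = _candidate_labels(a, b, by_iid, children_of)
                if not labels:
                    continue
                if len(labels) > 1:
                    logger.info(
                        "family %s pair (%s,%s): keeping %s, suppressing %s",
                        fid, a.iid, b.iid, labels[0][0],
                        ",".join(l[0] for l in labels[1:]),
                    )
                kind, senior = labels[0]
                out.append(_make_pair(fid, a, b, kind, senior))
    return out


def _candidate_labels(
    a: Individual,
    b: Individual,
    by_iid: dict[str, Individual],
    children_of: dict[str, set[str]],
) -> list[tuple[str, Individual]]:
    """All taxonomy relations holding for (a, b), in precedence order.

    Returns (relation-kind, senior-member) tuples; kind is one of
    RELATION_PRECEDENCE (sex-specific naming happens later).
    """
    found: list[tuple[str, Individual]] = []
    # spouse: >=1 shared offspring, opposite sexes (parental roles force sex)
    if children_of.get(a.iid, set()) & children_of.get(b.iid, set()):
        found.append(("spouse", a))
    if b.iid in _parents(a):
        found.append(("parent-offspring", b))
    elif a.iid in _parents(b):
        found.append(("parent-offspring", a))
    if _full_sibs(a, b):
        found.append(("full-sibling", a))
    elif _half_sibs(a, b):
        found.append(("half-sibling", a))
    a_grandparents = {
        g for p in _parents(a) for g in _parents(by_iid[p])
    }
    b_grandparents = {
        g for p in _parents(b) for g in _parents(by_iid[p])
    }
    if a.iid in b_grandparents:
        found.append(("grandparent", a))
    elif b.iid in a_grandparents:
        found.append(("grandparent", b))
    # avuncular: full sibling of a parent
    if any(_full_sibs(a, by_iid[p]) for p in _parents(b)):
        found.append(("avuncular", a))
    elif any(_full_sibs(b, by_iid[p]) for p in _parents(a)):
        found.append(("avuncular", b))
    # first cousins: a parent of each are full siblings (and not the same person)
    if any(
        pa != pb and _full_sibs(by_iid[pa], by_iid[pb])
        for pa in _parents(a)
        for pb in _parents(b)
    ):
        found.append(("cousin", a))
    found.sort(key=lambda t: RELATION_PRECEDENCE.index(t[0]))
    return found


def _make_pair(
    fid: str, a: Individual, b: Individual, kind: str, senior: Individual
) -> RelativePair:
    junior = b if senior is a else a
    if kind == "spouse":
        husband = a if a.sex == MALE else b
        wife = b if husband is a else a
        return RelativePair(fid, husband.iid, wife.iid, "spouse", "spouse")
    if kind == "parent-offspring":
        if senior.sex == UNKNOWN or junior.sex == UNKNOWN:
            return RelativePair(
                fid, senior.iid, junior.iid, "parent-offspring", "first", flagged=True
            )
        role = "father" if senior.sex == MALE else "mother"
        child = "son" if junior.sex == MALE else "daughter"
        return RelativePair(fid, senior.iid, junior.iid, f"{role}-{child}", "first")
    if kind == "full-sibling":
        sexes = {a.sex, b.sex}
        if UNKNOWN in sexes:
            return RelativePair(
                fid, a.iid, b.iid, "sibling", "first", flagged=True
            )
        if sexes == {FEMALE}:
            return RelativePair(fid, a.iid, b.iid, "sister-sister", "first")
        if sexes == {MALE}:
            return RelativePair(fid, a.iid, b.iid, "brother-brother", "first")
        brother = a if a.sex == MALE else b
        sister = b if brother is a else a
        return RelativePair(fid, brother.iid, sister.iid, "brother-sister", "first")
    if kind in ("half-sibling", "cousin"):
        return RelativePair(fid, a.iid, b.iid, kind, "second")
    # grandparent / avuncular: senior first
    return RelativePair(fid, senior.iid, junior.iid, kind, "second")


def pair_counts(pairs: Iterable[RelativePair]) -> dict[str, int]:
    """Pair tally by relation label."""
    counts: dict[str, int] = defaultdict(int)
    for p in pairs:
        counts[p.relation] += 1
    return dict(counts)


def write_pairs(pairs: Iterable[RelativePair], path) -> None:
    """Pair list as TSV (fid, iid_a, iid_b, relation, degree, flagged)."""
    with open(path, "w") as fh:
        fh.write("fid\tiid_a\tiid_b\trelation\tdegree\tflagged\n")
        for p in pairs:
            fh.write(
                f"{p.fid}\t{p.iid_a}\t{p.iid_b}\t{p.relation}\t{p.degree}"
                f"\t{int(p.flagged)}\n"
            )


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------


@dataclass
class PedigreeSummary:
    n_families: int
    n_individuals: int
    n_singletons: int
    mean_family_size: float
    sd_family_size: float
    min_family_size: int
    max_family_size: int
    n_sibships: int
    mean_sibship_size: float
    extra: dict = field(default_factory=dict)


def pedigree_summary(ped: Pedigree) -> PedigreeSummary:
    """Family-size and sibship bookkeeping in the shape cohort papers report.

    A sibship is a group of individuals sharing the same (named) father and
    mother; singleton children count as sibships of size one.
    """
    if len(ped) == 0:
        raise PedigreeError("empty pedigree")
    sizes = np.array([len(ped.family_members(f)) for f in ped.family_ids])
    sibships: dict[tuple[str, str, str], int] = defaultdict(int)
    for ind in ped:
        if ind.father is not None or ind.mother is not None:
            sibships[(ind.fid, ind.father or "", ind.mother or "")] += 1
    sib_sizes = np.array(list(sibships.values()), dtype=float)
    return PedigreeSummary(
        n_families=len(sizes),
        n_individuals=int(sizes.sum()),
        n_singletons=int((sizes == 1).sum()),
        mean_family_size=float(sizes.mean()),
        sd_family_size=float(sizes.std(ddof=1)) if len(sizes) > 1 else 0.0,
        min_family_size=int(sizes.min()),
        max_family_size=int(sizes.max()),
        n_sibships=len(sib_sizes),
        mean_sibship_size=float(sib_sizes.mean()) if len(sib_sizes) else 0.0,
    )
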