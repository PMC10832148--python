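"""Theoretical VAF-peak mathematics for allele-specific copy number QC.

The central quantity is the expected variant allele frequency (VAF) of a
somatic mutation present in ``m`` genome copies (its *multiplicity*) on a
segment with ``nA`` major and ``nB`` minor allele copies, in a bulk sample of
tumor purity ``pi`` where the mutation is carried by a fraction ``c`` of tumor
cells (its cancer cell fraction, CCF)::

    v_m(pi, c) = m * pi * c / (2 * (1 - pi) + pi * (nA + nB))

The denominator counts the expected reads per locus: two copies from each
admixed normal cell plus ``nA + nB`` copies from each tumor cell.  All peak
positions, error propagations between purity and VAF space, and subclonal
peak predictions in this module derive from this single equation.

For subclonal copy number segments (two tumor clones with proportions
``rho1 + rho2 = 1``) the module also enumerates the evolutionary models
(linear or branching paths of single-allele gains/losses and whole-genome
doubling from a diploid ancestor) and derives the multiplicity of mutations
shared by, or private to, each clone under every model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "ExpectedPeak",
    "EvolutionModel",
    "expected_vaf",
    "multiplicity_set",
    "peaks_for_karyotype",
    "vaf_error_from_purity_error",
    "purity_from_vaf",
    "purity_error_from_vaf_error",
    "enumerate_evolution_models",
    "subclonal_expected_peaks",
    "peak_positions",
    "SIMPLE_KARYOTYPES",
]

#: Allele-specific states treated as "simple": reachable in one evolutionary
#: step from a heterozygous diploid cell (single-allele gain or loss,
#: copy-neutral LOH, or whole-genome doubling).
SIMPLE_KARYOTYPES = frozenset({"1:0", "1:1", "2:0", "2:1", "2:2"})


@dataclass(frozen=True)
class ExpectedPeak:
    """A theoretical VAF peak.

    Parameters
    ----------
    vaf : float
        Peak position in (0, 1).
    multiplicity : int | tuple[int, int]
        Mutation multiplicity ``m`` (clonal / private subclonal peaks) or the
        pair ``(m1, m2)`` of per-clone multiplicities for shared subclonal
        mutations.
    origin : str
        ``"clonal"``, ``"subclonal_shared"`` or ``"subclonal_private"``.
    karyotype : str
        ``"nA:nB"`` label, or ``"nA1:nB1-nA2:nB2"`` for subclonal peaks.
    clone : int | None
        1-based clone index for private subclonal peaks.
    """

    vaf: float
    multiplicity: object
    origin: str = "clonal"
    karyotype: str = ""
    clone: int | None = None


def _validate_purity(purity: float) -> None:
    if not 0 < purity <= 1:
        raise ValueError(f"purity must be in (0, 1], got {purity}")


def expected_vaf(m: int, n_a: int, n_b: int, purity: float, ccf: float = 1.0) -> float:
    """Expected VAF of a mutation in ``m`` copies on an ``n_a:n_b`` segment.

    ``ccf`` is the fraction of tumor cells carrying the mutation (1 for
    clonal mutations).
    """
    _validate_purity(purity)
    if not 0 < ccf <= 1:
        raise ValueError(f"ccf must be in (0, 1], got {ccf}")
    if m < 1:
        raise ValueError(f"multiplicity must be >= 1, got {m}")
    denom = 2.0 * (1.0 - purity) + purity * (n_a + n_b)
    if denom <= 0:
        raise ValueError(
            f"degenerate segment: nA+nB = {n_a + n_b} with purity {purity}"
        )
    return m * purity * ccf / denom


def multiplicity_set(n_a: int, n_b: int) -> list[int]:
    """Legal mutation multiplicities for a clonal ``n_a:n_b`` segment.

    Simple states without an amplified allele (1:0, 1:1) only admit ``m = 1``;
    amplified simple states (2:0, 2:1, 2:2) admit ``m in {1, 2}``; for complex
    states every ``m`` from 1 to the larger allele count is tested.
    """
    if n_a < n_b:
        n_a, n_b = n_b, n_a
    if n_a < 0 or n_b < 0 or n_a + n_b == 0:
        raise ValueError(f"invalid allele counts {n_a}:{n_b}")
    label = f"{n_a}:{n_b}"
    if label in ("1:0", "1:1"):
        return [1]
    if label in ("2:0", "2:1", "2:2"):
        return [1, 2]
    return list(range(1, max(n_a, n_b) + 1))


def peaks_for_karyotype(n_a: int, n_b: int, purity: float) -> list[ExpectedPeak]:
    """All expected clonal peaks for a karyotype, ascending in multiplicity."""
    label = f"{max(n_a, n_b)}:{min(n_a, n_b)}"
    return [
        ExpectedPeak(
            vaf=expected_vaf(m, n_a, n_b, purity),
            multiplicity=m,
            origin="clonal",
            karyotype=label,
        )
        for m in multiplicity_set(n_a, n_b)
    ]


def vaf_error_from_purity_error(m: int, p: int, purity: float, epsilon: float) -> float:
    """First-order propagation of a purity error ``epsilon`` into VAF space.

    Linearizes ``v_m(pi)`` around ``pi`` for a segment of ploidy
    ``p = nA + nB``::

        dv = 2 * m * epsilon / (2 * (1 - pi) + pi * p) ** 2
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    _validate_purity(purity)
    denom = 2.0 * (1.0 - purity) + purity * p
    if denom <= 0:
        raise ValueError("degenerate ploidy/purity combination")
    return 2.0 * m * epsilon / denom**2


def purity_from_vaf(v: float, m: int, p: int) -> float:
    """Invert the clonal peak equation: purity implied by a peak at ``v``."""
    denom = m + (2 - p) * v
    if denom == 0:
        raise ValueError("division by zero inverting the peak equation")
    return 2.0 * v / denom


def purity_error_from_vaf_error(v: float, dv: float, m: int, p: int) -> float:
    """First-order propagation of a VAF offset ``dv`` into purity space.

    Signed: a data peak to the right of the expected peak (positive ``dv``)
    maps to a positive purity correction.  Composing with
    :func:`vaf_error_from_purity_error` at the same ``(m, p, purity)`` returns
    the original purity error exactly.
    """
    denom = m + v * (2 - p)
    if denom == 0:
        raise ValueError("division by zero in purity error propagation")
    return 2.0 * m * dv / denom**2


# ---------------------------------------------------------------------------
# Evolution models for two-subclone segments
# ---------------------------------------------------------------------------

# Allele-labelled copy states are ordered pairs (a, b): copies of the two
# parental alleles A and B.  Events: duplicate one existing copy of an allele,
# remove one copy, or double the whole genome (WGD).  Copy-neutral LOH (1:1 ->
# 2:0) is reachable in two steps; treating it as one composite step would not
# change any multiplicity outcome, so the alphabet is kept minimal.

_MAX_COPIES = 4  # search cap; simple + mirrored states never exceed 2 per allele


def _parse_state(label: str) -> tuple[int, int]:
    try:
        a, b = (int(x) for x in label.split(":"))
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"malformed karyotype label {label!r}") from exc
    if a < 0 or b < 0 or a + b == 0:
        raise ValueError(f"invalid karyotype {label!r}")
    return a, b


def _orientations(label: str) -> list[tuple[int, int]]:
    a, b = _parse_state(label)
    return [(a, b)] if a == b else [(a, b), (b, a)]


def _neighbours(state: tuple[int, int]) -> list[tuple[str, tuple[int, int]]]:
    a, b = state
    out = []
    if 1 <= a < _MAX_COPIES:
        out.append((("gain", 0), (a + 1, b)))
    if 1 <= b < _MAX_COPIES:
        out.append((("gain", 1), (a, b + 1)))
    if a >= 1:
        out.append((("loss", 0), (a - 1, b)))
    if b >= 1:
        out.append((("loss", 1), (a, b - 1)))
    if 0 < a + b and 2 * a <= _MAX_COPIES and 2 * b <= _MAX_COPIES:
        out.append((("wgd", None), (2 * a, 2 * b)))
    return out


def _shortest_paths(src: tuple[int, int], dst: tuple[int, int]) -> list[list[tuple]]:
    """All shortest event sequences from ``src`` to ``dst`` (may be empty)."""
    if src == dst:
        return [[]]
    frontier = {src: [[]]}
    seen = {src}
    for _ in range(8):
        nxt: dict[tuple[int, int], list[list[tuple]]] = {}
        for state, paths in frontier.items():
            for event, new in _neighbours(state):
                if new in seen:
                    continue
                nxt.setdefault(new, []).extend(p + [event] for p in paths)
        if dst in nxt:
            return nxt[dst]
        seen.update(nxt)
        frontier = nxt
        if not frontier:
            break
    return []


class _Copy:
    __slots__ = ("cid", "allele", "parent", "born")

    def __init__(self, cid, allele, parent, born):
        self.cid = cid
        self.allele = allele
        self.parent = parent
        self.born = born


class _Lineage:
    """Concrete copy-level replay of an event sequence with explicit choices."""

    def __init__(self, start: tuple[int, int]):
        self.copies: dict[int, _Copy] = {}
        self._next = 0
        self.alive: list[set[int]] = []
        first = set()
        for allele, n in enumerate(start):
            for _ in range(n):
                first.add(self._new(allele, None, 0))
        self.alive.append(first)

    def _new(self, allele, parent, born):
        cid = self._next
        self._next += 1
        self.copies[cid] = _Copy(cid, allele, parent, born)
        return cid

    def clone(self) -> "_Lineage":
        other = _Lineage.__new__(_Lineage)
        other.copies = dict(self.copies)
        other._next = self._next
        other.alive = [set(s) for s in self.alive]
        return other

    def apply_variants(self, event) -> list["_Lineage"]:
        """All concrete instantiations of one abstract event."""
        kind, allele = event
        cur = self.alive[-1]
        epoch = len(self.alive)
        out = []
        if kind == "wgd":
            nxt = self.clone()
            new_alive = set(cur)
            for cid in cur:
                new_alive.add(nxt._new(self.copies[cid].allele, cid, epoch))
            nxt.alive.append(new_alive)
            return [nxt]
        pool = [c for c in cur if self.copies[c].allele == allele]
        for chosen in pool:
            nxt = self.clone()
            new_alive = set(cur)
            if kind == "gain":
                new_alive.add(nxt._new(allele, chosen, epoch))
            else:  # loss
                new_alive.discard(chosen)
            nxt.alive.append(new_alive)
            out.append(nxt)
        return out

    def ancestor_at(self, cid: int, epoch: int) -> int:
        c = self.copies[cid]
        while c.born > epoch:
            c = self.copies[c.parent]
        return c.cid

    def descendants_of(self, cid: int, epoch: int) -> int:
        return sum(1 for e in self.alive[-1] if self.ancestor_at(e, epoch) == cid)


def _replay_all(start: tuple[int, int], events: Sequence[tuple]) -> list[_Lineage]:
    lineages = [_Lineage(start)]
    for ev in events:
        lineages = [nxt for lin in lineages for nxt in lin.apply_variants(ev)]
    return lineages


@dataclass(frozen=True)
class EvolutionModel:
    """One ancestor-to-two-subclones copy number evolution scenario.

    ``clone1``/``clone2`` are allele-labelled states ``(a, b)``; the
    karyotype labels are the unordered ``major:minor`` strings.
    ``shared_multiplicities`` holds ``(m1, m2)`` pairs for mutations
    accumulated before the clones diverged (entries with a zero component are
    present only in one clone and coincide with private peaks);
    ``private_multiplicities`` holds per-clone multiplicity sets for
    mutations acquired after the divergence.
    """

    topology: str  # "linear" or "branching"
    ancestor: tuple[int, int]
    clone1: tuple[int, int]
    clone2: tuple[int, int]
    pre_split_events: tuple = ()
    clone1_events: tuple = ()
    clone2_events: tuple = ()
    shared_multiplicities: frozenset = frozenset()
    private_multiplicities: tuple = (frozenset(), frozenset())

    @property
    def karyotype1(self) -> str:
        a, b = self.clone1
        return f"{max(a, b)}:{min(a, b)}"

    @property
    def karyotype2(self) -> str:
        a, b = self.clone2
        return f"{max(a, b)}:{min(a, b)}"

    def describe(self) -> str:
        def fmt(state):
            a, b = state
            return "A" * a + "B" * b or "0"

        if self.topology == "branching":
            return f"{fmt(self.ancestor)} -> {fmt(self.clone1)} | {fmt(self.clone2)}"
        # the intermediate clone is the one without post-split events
        if self.clone1_events:
            mid, tip = self.clone2, self.clone1
        else:
            mid, tip = self.clone1, self.clone2
        return f"{fmt(self.ancestor)} -> {fmt(mid)} -> {fmt(tip)}"

    def to_dict(self) -> dict:
        return {
            "topology": self.topology,
            "description": self.describe(),
            "clone1": self.karyotype1,
            "clone2": self.karyotype2,
            "shared_multiplicities": sorted(self.shared_multiplicities),
            "private_multiplicities": [
                sorted(s) for s in self.private_multiplicities
            ],
        }


def _multiplicities_for(
    ancestor: tuple[int, int],
    pre: Sequence[tuple],
    b1: Sequence[tuple],
    b2: Sequence[tuple],
) -> tuple[frozenset, frozenset, frozenset]:
    """Shared (m1, m2) pairs and per-clone private multiplicity sets.

    Mutations are placed on every copy alive at every epoch; a later gain of
    the mutated copy doubles the mutation, a loss may remove it.  All
    concrete event instantiations (which copy is duplicated/lost) are
    enumerated and their outcomes pooled.
    """
    shared: set[tuple[int, int]] = set()
    priv1: set[int] = set()
    priv2: set[int] = set()
    for trunk in _replay_all(ancestor, pre):
        split_epoch = len(trunk.alive) - 1
        ends1 = _replay_all_from(trunk, b1)
        ends2 = _replay_all_from(trunk, b2)
        for l1, l2 in itertools.product(ends1, ends2):
            # mutations before the split: multiplicity in both clones
            for epoch in range(split_epoch + 1):
                for cid in _alive_at(trunk, epoch):
                    m1 = l1.descendants_of(cid, epoch)
                    m2 = l2.descendants_of(cid, epoch)
                    if m1 + m2 > 0:
                        shared.add((m1, m2))
            # private mutations: epochs at/after the split, own branch only
            for lin, priv in ((l1, priv1), (l2, priv2)):
                for epoch in range(split_epoch, len(lin.alive)):
                    for cid in lin.alive[epoch]:
                        m = lin.descendants_of(cid, epoch)
                        if m > 0:
                            priv.add(m)
    return frozenset(shared), frozenset(priv1), frozenset(priv2)


def _alive_at(lineage: _Lineage, epoch: int) -> set[int]:
    return lineage.alive[epoch]


def _replay_all_from(trunk: _Lineage, events: Sequence[tuple]) -> list[_Lineage]:
    lineages = [trunk.clone()]
    for ev in events:
        lineages = [nxt for lin in lineages for nxt in lin.apply_variants(ev)]
    return lineages


def _swap(state: tuple[int, int]) -> tuple[int, int]:
    return state[1], state[0]


def enumerate_evolution_models(
    state1: str, state2: str, ancestor: str = "1:1"
) -> list[EvolutionModel]:
    """Enumerate linear and branching evolution models for two subclones.

    Models are shortest single-allele-event paths in the allele-labelled copy
    state graph; scenarios differing only by the global A/B relabelling are
    reported once, while genuinely mirrored amplifications (e.g. AAB | ABB)
    are distinct models.  A state with zero copies of an allele can never
    regain it, so e.g. no linear model evolves a trisomy out of a
    copy-neutral LOH.
    """
    anc = _parse_state(ancestor)
    models: dict[tuple, EvolutionModel] = {}

    def add(topology, o1, o2, pre, b1, b2):
        shared, p1, p2 = _multiplicities_for(anc, pre, b1, b2)
        key_direct = (topology, o1, o2, shared, p1, p2)
        key_mirror = (
            topology,
            _swap(o1),
            _swap(o2),
            frozenset(shared),
            p1,
            p2,
        )
        if key_direct in models or key_mirror in models:
            return
        models[key_direct] = EvolutionModel(
            topology=topology,
            ancestor=anc,
            clone1=o1,
            clone2=o2,
            pre_split_events=tuple(pre),
            clone1_events=tuple(b1),
            clone2_events=tuple(b2),
            shared_multiplicities=shared,
            private_multiplicities=(p1, p2),
        )

    # Collect candidate scenarios per topology/direction, then retain only
    # the orientation variants realizable with the fewest total events.
    branching: list[tuple[int, tuple]] = []
    linear_12: list[tuple[int, tuple]] = []  # ancestor -> state1 -> state2
    linear_21: list[tuple[int, tuple]] = []  # ancestor -> state2 -> state1
    seen_branching: set[tuple] = set()
    for o1 in _orientations(state1):
        for o2 in _orientations(state2):
            paths1 = _shortest_paths(anc, o1)
            paths2 = _shortest_paths(anc, o2)
            # global allele-relabelling symmetry for branching scenarios
            canon = min((o1, o2), (_swap(o1), _swap(o2)))
            if paths1 and paths2 and canon not in seen_branching:
                seen_branching.add(canon)
                for p1_, p2_ in itertools.product(paths1, paths2):
                    branching.append(
                        (len(p1_) + len(p2_), (o1, o2, [], p1_, p2_))
                    )
            if paths1:
                for pre, tail in itertools.product(
                    paths1, _shortest_paths(o1, o2)
                ):
                    linear_12.append(
                        (len(pre) + len(tail), (o1, o2, pre, [], tail))
                    )
            if paths2:
                for pre, tail in itertools.product(
                    paths2, _shortest_paths(o2, o1)
                ):
                    linear_21.append(
                        (len(pre) + len(tail), (o1, o2, pre, tail, []))
                    )

    for topology, cands in (
        ("branching", branching),
        ("linear", linear_12),
        ("linear", linear_21),
    ):
        if not cands:
            continue
        best = min(length for length, _ in cands)
        for length, (o1, o2, pre, b1, b2) in cands:
            if length == best:
                add(topology, o1, o2, pre, b1, b2)

    # deterministic ordering: branching first, then by description
    out = sorted(
        models.values(), key=lambda m: (m.topology != "branching", m.describe())
    )
    return out


def subclonal_expected_peaks(
    model: EvolutionModel, rho1: float, rho2: float, purity: float
) -> list[ExpectedPeak]:
    """Expected VAF peaks for a two-subclone segment under ``model``.

    Shared mutations with per-clone multiplicities ``(m1, m2)`` peak at::

        v = (m1*rho1 + m2*rho2) * pi / (2*(1-pi) + pi*(rho1*p1 + rho2*p2))

    with ``p_i`` the ploidy of clone ``i``; private mutations of clone ``i``
    use ``m_i * rho_i`` in the numerator.  Peaks at duplicate positions are
    collapsed, keeping every provenance.
    """
    if abs(rho1 + rho2 - 1.0) > 1e-6:
        raise ValueError("clone proportions must sum to 1")
    if not (0 < rho1 < 1):
        raise ValueError("clone proportions must be in (0, 1)")
    _validate_purity(purity)
    p1 = sum(model.clone1)
    p2 = sum(model.clone2)
    denom = 2.0 * (1.0 - purity) + purity * (rho1 * p1 + rho2 * p2)
    kar = f"{model.karyotype1}-{model.karyotype2}"

    raw: list[ExpectedPeak] = []
    for m1, m2 in sorted(model.shared_multiplicities):
        v = (m1 * rho1 + m2 * rho2) * purity / denom
        if m1 > 0 and m2 > 0:
            raw.append(ExpectedPeak(v, (m1, m2), "subclonal_shared", kar))
        # pairs with a zero component coincide with private peaks below
    for clone_idx, (rho, priv) in enumerate(
        ((rho1, model.private_multiplicities[0]), (rho2, model.private_multiplicities[1])),
        start=1,
    ):
        for m in sorted(priv):
            v = m * rho * purity / denom
            raw.append(
                ExpectedPeak(v, m, "subclonal_private", kar, clone=clone_idx)
            )

    # collapse duplicate positions, keep first provenance
    seen: dict[int, ExpectedPeak] = {}
    for pk in raw:
        key = round(pk.vaf * 1e9)
        if key not in seen:
            seen[key] = pk
    return sorted(seen.values(), key=lambda p: p.vaf)


def peak_positions(peaks: Iterable[ExpectedPeak], ndigits: int = 9) -> list[float]:
    """Sorted unique peak positions (utility for model comparison)."""
    return sorted({round(p.vaf, ndigits) for p in peaks})
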