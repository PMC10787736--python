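"""Labeled name-pair generation: perturbation, balancing, splitting.

Training a character-level metric model requires pairs ``(query, target,
label)`` with label ``0`` for names referring to the same natural product
(common name, Latin binomial, spelling variants of either) and label ``1``
for names of different products. Real annotated pairs are scarce, so the
pipeline augments them with a stochastic misspelling generator: 40% of the
characters of a name are selected and each receives one of five actions
drawn uniformly — substitute, delete, insert-after, transpose-with-previous,
or no change — mimicking the typo distribution of free-text report fields.

Two balancing passes follow: per-target balancing (no target name should
dominate) and label balancing (matching vs non-matching pairs ~50/50),
after which the data is split 70/30 into train/validation with an optional
label-stratified holdout set.

The module doubles as the synthetic-fixture generator: :func:`synth_lexicon`
fabricates groups of equivalent pseudo-botanical names (a two-word Latin
binomial, a common name, and perturbation-derived variants) and
:func:`synth_decoy_corpus` fabricates unrelated strings that emulate the
non-NP bulk of an unmapped drug-name corpus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import normalize
from .errors import DegenerateName, InsufficientGroups, TooFewPairs

_ALPHABET = [chr(ord("A") + i) for i in range(26)] + [" "]


@dataclass(frozen=True)
class NameGroup:
    """A set of names treated as equivalent (one natural product)."""

    group_id: str
    preferred_term: str
    latin_binomial: str
    variants: tuple[str, ...] = ()

    @property
    def names(self) -> tuple[str, ...]:
        return (self.preferred_term, self.latin_binomial) + self.variants


@dataclass
class Lexicon:
    """A list of :class:`NameGroup` with unique ids."""

    groups: list[NameGroup]

    def __post_init__(self) -> None:
        ids = [g.group_id for g in self.groups]
        if len(set(ids)) != len(ids):
            raise ValueError("group ids must be unique")

    def all_names(self) -> list[str]:
        return [n for g in self.groups for n in g.names]

    def group_of(self) -> dict[str, str]:
        """Map each name to its group id (first group wins on collision)."""
        out: dict[str, str] = {}
        for g in self.groups:
            for n in g.names:
                out.setdefault(n, g.group_id)
        return out

    def to_csv(self, path: str | Path) -> None:
        """Write the ``group_id,preferred_term,latin_binomial,variant`` schema."""
        import csv

        with Path(path).open("w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(["group_id", "preferred_term", "latin_binomial", "variant"])
            for g in self.groups:
                if g.variants:
                    for v in g.variants:
                        w.writerow([g.group_id, g.preferred_term, g.latin_binomial, v])
                else:
                    w.writerow([g.group_id, g.preferred_term, g.latin_binomial, ""])

    @classmethod
    def from_csv(cls, path: str | Path) -> "Lexicon":
        import csv

        rows: dict[str, dict] = {}
        with Path(path).open(newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                g = rows.setdefault(
                    row["group_id"],
                    {
                        "preferred_term": normalize.clean_name(row["preferred_term"]),
                        "latin_binomial": normalize.clean_name(row["latin_binomial"]),
                        "variants": [],
                    },
                )
                if row.get("variant"):
                    g["variants"].append(normalize.clean_name(row["variant"]))
        groups = [
            NameGroup(gid, d["preferred_term"], d["latin_binomial"], tuple(d["variants"]))
            for gid, d in rows.items()
        ]
        return cls(groups)


@dataclass(frozen=True)
class LabeledPair:
    """A training unit: label 0 = matching (same group), 1 = distant."""

    query: str
    target: str
    label: int


@dataclass
class PerturbationConfig:
    """Parameters of the stochastic misspelling procedure.

    ``selection_rate`` is the fraction of character positions selected for
    modification (default 0.4). The five action intervals partition [0, 1]:
    ``[0, 0.2)`` substitute, ``[0.2, 0.4)`` delete, ``[0.4, 0.6)`` insert
    after, ``[0.6, 0.8)`` transpose with previous, ``[0.8, 1]`` no change.
    """

    selection_rate: float = 0.4
    intervals: tuple[float, float, float, float] = (0.2, 0.4, 0.6, 0.8)
    rng_seed: int = 0
    max_len: int = normalize.MAX_LEN
    max_retries: int = 20

    def __post_init__(self) -> None:
        if not 0.0 < self.selection_rate <= 1.0:
            raise ValueError("selection_rate must be in (0, 1]")
        if list(self.intervals) != sorted(self.intervals) or not all(
            0.0 < b < 1.0 for b in self.intervals
        ):
            raise ValueError("interval boundaries must be increasing within (0, 1)")


@dataclass
class PairDataset:
    """Train/validation(/holdout) splits plus provenance metadata."""

    train: list[LabeledPair]
    validation: list[LabeledPair]
    holdout: list[LabeledPair]
    manifest: dict = field(default_factory=dict)

    def to_dir(self, path: str | Path) -> None:
        import csv

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for split, pairs in (
            ("train", self.train),
            ("validation", self.validation),
            ("holdout", self.holdout),
        ):
            with (path / f"{split}.csv").open("w", newline="", encoding="utf-8") as fh:
                w = csv.writer(fh, lineterminator="\n")
                w.writerow(["query", "target", "label"])
                for p in pairs:
                    w.writerow([p.query, p.target, p.label])
        (path / "manifest.json").write_text(json.dumps(self.manifest, indent=2))

    @classmethod
    def from_dir(cls, path: str | Path) -> "PairDataset":
        import csv

        path = Path(path)
        splits = {}
        for split in ("train", "validation", "holdout"):
            with (path / f"{split}.csv").open(newline="", encoding="utf-8") as fh:
                splits[split] = [
                    LabeledPair(r["query"], r["target"], int(r["label"]))
                    for r in csv.DictReader(fh)
                ]
        manifest = json.loads((path / "manifest.json").read_text())
        return cls(splits["train"], splits["validation"], splits["holdout"], manifest)


def matching_fraction(pairs: Sequence[LabeledPair]) -> float:
    """Fraction of pairs with label 0 (matching)."""
    return sum(1 for p in pairs if p.label == 0) / len(pairs)


def _perturb_once(name: str, config: PerturbationConfig, rng: np.random.Generator):
    """One perturbation draw; returns (raw result, per-position action log)."""
    n = len(name)
    k = max(1, round(config.selection_rate * n))
    positions = sorted(rng.choice(n, size=min(k, n), replace=False).tolist())
    draws = rng.uniform(0.0, 1.0, size=len(positions))
    b = config.intervals
    chars = list(name)
    actions: list[str] = []
    # Positions are selected on the original string; edits are applied
    # right-to-left so earlier indices remain valid as the list shifts.
    for pos, u in reversed(list(zip(positions, draws))):
        if u < b[0]:
            old = chars[pos]
            chars[pos] = _ALPHABET[rng.integers(len(_ALPHABET))]
            actions.append("substitute" if chars[pos] != old else "substitute_same")
        elif u < b[1]:
            del chars[pos]
            actions.append("delete")
        elif u < b[2]:
            chars.insert(pos + 1, _ALPHABET[rng.integers(len(_ALPHABET))])
            actions.append("insert")
        elif u < b[3]:
            if pos > 0:
                chars[pos - 1], chars[pos] = chars[pos], chars[pos - 1]
                actions.append("transpose")
            else:
                actions.append("transpose_noop")
        else:
            actions.append("noop")
    return "".join(chars), actions[::-1]


def perturb_name(
    name: str,
    config: PerturbationConfig,
    rng: np.random.Generator | None = None,
    *,
    return_actions: bool = False,
):
    """Apply the stochastic misspelling procedure to a clean name.

    Selects ``k = max(1, round(selection_rate * len(name)))`` distinct
    positions and applies an independently drawn action to each. The
    result is re-cleaned; candidates that clean to empty or exceed the
    length cutoff are rejected and redrawn.

    Raises
    ------
    DegenerateName
        If every retry yields an unusable string (e.g. a one-letter name
        that keeps being deleted).
    """
    if not name:
        raise ValueError("cannot perturb an empty name")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    for _ in range(config.max_retries):
        raw, actions = _perturb_once(name, config, rng)
        try:
            cleaned = normalize.clean_name(raw, max_len=config.max_len)
        except Exception:
            continue
        return (cleaned, actions) if return_actions else cleaned
    raise DegenerateName(f"could not perturb {name!r} into a usable string")


def generate_pairs(
    lexicon: Lexicon,
    pairs_per_group: int,
    config: PerturbationConfig,
    rng: np.random.Generator | None = None,
) -> list[LabeledPair]:
    """Build an initial matching-pair set from a lexicon.

    For each group, the query pool starts as the group's names and grows
    with perturbation-derived misspellings; every pool string is paired
    with *all* names of its group (label 0), so pair counts are
    combinatorial in pool size and the same query string recurs across
    many pairs — the structure that lets a modest name set yield a large
    pair set. Duplicate ``(query, target, label)`` triples are suppressed.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    seen: set[tuple[str, str, int]] = set()
    pairs: list[LabeledPair] = []

    def add(q: str, t: str, label: int) -> bool:
        key = (q, t, label)
        if key in seen or q == t:
            return False
        seen.add(key)
        pairs.append(LabeledPair(q, t, label))
        return True

    for group in lexicon.groups:
        count = 0
        names = group.names
        pool: set[str] = set(names)
        for a in names:
            for b_ in names:
                if a != b_ and add(a, b_, 0):
                    count += 1
        attempts = 0
        while count < pairs_per_group and attempts < 50 * pairs_per_group:
            attempts += 1
            base = names[rng.integers(len(names))]
            try:
                query = perturb_name(base, config, rng)
            except DegenerateName:
                continue
            if query in pool:
                continue
            pool.add(query)
            for target in names:
                if add(query, target, 0):
                    count += 1
    return pairs


def _query_pools(pairs: Sequence[LabeledPair], lexicon: Lexicon) -> dict[str, set[str]]:
    """Per-group query strings observed in matching pairs (plus the names)."""
    target_group = lexicon.group_of()
    pools: dict[str, set[str]] = {g.group_id: set(g.names) for g in lexicon.groups}
    for p in pairs:
        if p.label == 0:
            gid = target_group.get(p.target)
            if gid is not None:
                pools[gid].add(p.query)
    return pools


def _target_counts(pairs: Sequence[LabeledPair]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for p in pairs:
        if p.label == 0:
            counts[p.target] = counts.get(p.target, 0) + 1
    return counts


def balance_targets(
    pairs: list[LabeledPair],
    lexicon: Lexicon,
    config: PerturbationConfig,
    rng: np.random.Generator | None = None,
    *,
    tolerance: float = 0.1,
) -> list[LabeledPair]:
    """Top up under-represented target names with synthesized matching pairs.

    New unique pairs are created by pairing the target with misspelled
    names from its group — reusing the group's existing query pool first,
    then fresh perturbations — until every target's matching-pair count
    is within ``tolerance`` (default +-10%) of the maximum target count.
    """
    if not pairs:
        raise ValueError("pairs must be non-empty")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    out = list(pairs)
    seen = {(p.query, p.target, p.label) for p in out}
    counts = _target_counts(out)
    if not counts:
        return out
    group_names = {g.group_id: g.names for g in lexicon.groups}
    target_group = lexicon.group_of()
    pools = _query_pools(out, lexicon)
    goal = max(counts.values())
    floor = int(np.ceil((1.0 - tolerance) * goal))
    for target, count in sorted(counts.items()):
        gid = target_group.get(target)
        if gid is None:
            continue
        names = group_names[gid]
        for query in sorted(pools.get(gid, ())):
            if count >= floor:
                break
            key = (query, target, 0)
            if key in seen or query == target:
                continue
            seen.add(key)
            out.append(LabeledPair(query, target, 0))
            count += 1
        attempts = 0
        while count < floor and attempts < 50 * goal:
            attempts += 1
            base = names[rng.integers(len(names))]
            try:
                query = perturb_name(base, config, rng)
            except DegenerateName:
                continue
            key = (query, target, 0)
            if key in seen or query == target:
                continue
            seen.add(key)
            pools.setdefault(gid, set()).add(query)
            out.append(LabeledPair(query, target, 0))
            count += 1
    return out


def balance_labels(
    pairs: list[LabeledPair],
    lexicon: Lexicon,
    config: PerturbationConfig,
    rng: np.random.Generator | None = None,
    *,
    band: tuple[float, float] = (0.49, 0.51),
) -> list[LabeledPair]:
    """Synthesize pairs until the matching fraction falls inside ``band``.

    Non-matching pairs draw the query from one group's query pool (its
    names plus the misspellings already appearing in matching pairs) and
    the target from a different group's names; matching pairs are
    synthesized as in :func:`balance_targets`. Synthesis continues to a
    narrow interior band around the midpoint of ``band`` so that drawing
    a 50/50-stratified holdout afterwards cannot push any split outside
    ``band``.

    Raises
    ------
    InsufficientGroups
        If non-matching pairs are needed but the lexicon has one group.
    """
    if not pairs:
        raise ValueError("pairs must be non-empty")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    out = list(pairs)
    seen = {(p.query, p.target, p.label) for p in out}
    lo, hi = band
    mid = 0.5 * (lo + hi)
    stop_lo = max(lo, mid - 0.003)
    stop_hi = min(hi, mid + 0.003)
    groups = lexicon.groups
    pools = _query_pools(out, lexicon)
    pool_lists = {gid: sorted(qs) for gid, qs in pools.items()}

    def synth(label: int) -> LabeledPair | None:
        if label == 1:
            gi, gj = rng.choice(len(groups), size=2, replace=False)
            q_pool = pool_lists[groups[gi].group_id]
            t_names = groups[gj].names
        else:
            gi = rng.integers(len(groups))
            q_pool = pool_lists[groups[gi].group_id]
            t_names = groups[gi].names
        query = q_pool[rng.integers(len(q_pool))]
        target = t_names[rng.integers(len(t_names))]
        key = (query, target, label)
        if key in seen or query == target:
            return None
        seen.add(key)
        return LabeledPair(query, target, label)

    n_match = sum(1 for p in out if p.label == 0)
    attempts = 0
    max_attempts = 100 * (len(out) + 10)
    while not (stop_lo <= n_match / len(out) <= stop_hi) and attempts < max_attempts:
        attempts += 1
        add_label = 0 if n_match / len(out) < stop_lo else 1
        if add_label == 1 and len(groups) < 2:
            raise InsufficientGroups("need >=2 groups to synthesize non-matching pairs")
        made = synth(add_label)
        if made is None:
            continue
        out.append(made)
        if made.label == 0:
            n_match += 1
    return out


def make_splits(
    pairs: Sequence[LabeledPair],
    seed: int,
    holdout_n: int = 0,
    *,
    train_fraction: float = 0.7,
) -> PairDataset:
    """Split pairs into train/validation(/holdout).

    A label-stratified holdout of ``holdout_n`` pairs (~50/50 matching)
    is drawn first; the remainder is split 70/30 at random, stratified by
    label so every split inherits the balanced matching fraction.

    Raises
    ------
    TooFewPairs
        If ``holdout_n >= len(pairs)``.
    """
    pairs = list(pairs)
    if holdout_n >= len(pairs) or holdout_n < 0:
        raise TooFewPairs(f"cannot hold out {holdout_n} of {len(pairs)} pairs")
    rng = np.random.default_rng(seed)
    holdout: list[LabeledPair] = []
    remainder: list[LabeledPair] = []
    if holdout_n:
        by_label = {0: [], 1: []}
        for p in pairs:
            by_label[p.label].append(p)
        half = holdout_n // 2
        want = {0: half, 1: holdout_n - half}
        for label in (0, 1):
            pool = by_label[label]
            take = min(want[label], len(pool))
            idx = set(rng.choice(len(pool), size=take, replace=False).tolist())
            for i, p in enumerate(pool):
                (holdout if i in idx else remainder).append(p)
    else:
        remainder = pairs
    train: list[LabeledPair] = []
    validation: list[LabeledPair] = []
    for label in (0, 1):
        pool = [p for p in remainder if p.label == label]
        order = rng.permutation(len(pool))
        n_train = round(train_fraction * len(pool))
        train.extend(pool[i] for i in order[:n_train])
        validation.extend(pool[i] for i in order[n_train:])
    # interleave labels so minibatches are mixed even without shuffling
    train = [train[i] for i in rng.permutation(len(train))]
    validation = [validation[i] for i in rng.permutation(len(validation))]
    manifest = {
        "seed": int(seed),
        "holdout_n": int(holdout_n),
        "train_fraction": train_fraction,
        "sizes": {
            "train": len(train),
            "validation": len(validation),
            "holdout": len(holdout),
        },
        "matching_fraction": {
            split: matching_fraction(ps) if ps else None
            for split, ps in (("train", train), ("validation", validation), ("holdout", holdout))
        },
        # Balancing happens before splitting; the same underlying name may
        # appear in more than one split (pair sets, not name sets, are disjoint).
        "split_order": "holdout_first_then_70_30",
    }
    return PairDataset(train, validation, holdout, manifest)


# ---------------------------------------------------------------------------
# Synthetic fixtures


_ONSETS = ["B", "C", "D", "F", "G", "H", "K", "L", "M", "N", "P", "R", "S", "T", "V", "Z",
           "TH", "CH", "PH", "GL", "TR", "BR"]
_VOWELS = ["A", "E", "I", "O", "U"]
_LATIN_SUFFIX = ["UM", "US", "A", "IS", "ENSIS", "OIDES", "ATA", "IFOLIA"]


def _pseudo_word(rng: np.random.Generator, syllables: int) -> str:
    parts = [
        _ONSETS[rng.integers(len(_ONSETS))] + _VOWELS[rng.integers(len(_VOWELS))]
        for _ in range(syllables)
    ]
    return "".join(parts)


def _latin_word(rng: np.random.Generator, syllables: int) -> str:
    return _pseudo_word(rng, syllables) + _LATIN_SUFFIX[rng.integers(len(_LATIN_SUFFIX))]


def synth_lexicon(
    n_groups: int,
    seed: int,
    config: PerturbationConfig | None = None,
) -> Lexicon:
    """Fabricate a lexicon of pseudo-botanical name groups.

    Each group carries a two-word pseudo-Latin binomial, a common name,
    and 2-5 variants derived from the two by perturbation. Deterministic
    given ``(n_groups, seed)``.
    """
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    rng = np.random.default_rng(seed)
    if config is None:
        config = PerturbationConfig(rng_seed=seed)
    groups: list[NameGroup] = []
    used: set[str] = set()
    gid = 0
    while len(groups) < n_groups:
        binomial = f"{_latin_word(rng, int(rng.integers(2, 4)))} {_latin_word(rng, int(rng.integers(2, 4)))}"
        common = _pseudo_word(rng, int(rng.integers(2, 5)))
        if rng.uniform() < 0.3:
            common = common + " " + _pseudo_word(rng, 2)
        if binomial in used or common in used or len(binomial) > normalize.MAX_LEN:
            continue
        bases = [common, binomial]
        variants: list[str] = []
        n_var = int(rng.integers(2, 6))
        attempts = 0
        while len(variants) < n_var and attempts < 40:
            attempts += 1
            try:
                v = perturb_name(bases[rng.integers(2)], config, rng)
            except DegenerateName:
                continue
            if v not in used and v not in bases and v not in variants:
                variants.append(v)
        for n in bases + variants:
            used.add(n)
        groups.append(NameGroup(f"NP{gid:04d}", common, binomial, tuple(variants)))
        gid += 1
    return Lexicon(groups)


_DRUG_ONSETS = ["PR", "TR", "CL", "FL", "BR", "DR", "X", "Z", "V", "QU", "SPIR",
                "METH", "CARB", "SULF", "HYDR", "OX", "PHEN", "CHLOR", "AMF", "LEV"]
_DRUG_MIDS = ["A", "O", "I", "E", "AMI", "OXI", "ETHA", "ILLI", "AZO", "UTA"]
_DRUG_SUFFIX = ["OL", "INE", "IDE", "IUM", "ATE", "AN", "EX", "ONE", "MAB", "PRIL",
                "OLOL", "AZOLE", "ICIN", "MYCIN", "STATIN"]


def _drug_word(rng: np.random.Generator) -> str:
    onset = _DRUG_ONSETS[rng.integers(len(_DRUG_ONSETS))]
    mids = "".join(
        _DRUG_MIDS[rng.integers(len(_DRUG_MIDS))] for _ in range(rng.integers(1, 3))
    )
    return onset + mids + _DRUG_SUFFIX[rng.integers(len(_DRUG_SUFFIX))]


def synth_decoy_corpus(n: int, seed: int, *, avoid: set[str] | None = None) -> list[str]:
    """Fabricate ``n`` unrelated clean strings (non-NP corpus noise).

    Emulates the bulk of an unmapped drug-name corpus: pharmaceutical-style
    coinages (onset + infix + drug suffix), occasionally two tokens, drawn
    from a different letter-statistics model than the botanical name
    generator — mirroring the fact that most unmapped report strings are
    conventional drug names rather than natural-product names. Strings in
    ``avoid`` are never emitted.
    """
    rng = np.random.default_rng(seed)
    avoid = set(avoid or ())
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        word = _drug_word(rng)
        if rng.uniform() < 0.3:
            word = word + " " + _drug_word(rng)
        if word in seen or word in avoid or len(word) > normalize.MAX_LEN:
            continue
        seen.add(word)
        out.append(word)
    return out


def build_dataset(
    lexicon: Lexicon,
    config: PerturbationConfig,
    *,
    pairs_per_group: int = 100,
    holdout_n: int = 0,
    seed: int | None = None,
) -> PairDataset:
    """End-to-end dataset construction: generate, balance, split.

    Convenience wrapper chaining :func:`generate_pairs`,
    :func:`balance_targets`, :func:`balance_labels` and
    :func:`make_splits` with a single RNG stream.
    """
    if seed is None:
        seed = config.rng_seed
    rng = np.random.default_rng(seed)
    pairs = generate_pairs(lexicon, pairs_per_group, config, rng)
    pairs = balance_targets(pairs, lexicon, config, rng)
    pairs = balance_labels(pairs, lexicon, config, rng)
    ds = make_splits(pairs, seed=seed, holdout_n=holdout_n)
    ds.manifest.update(
        {
            "n_groups": len(lexicon.groups),
            "pairs_per_group": pairs_per_group,
            "selection_rate": config.selection_rate,
            "intervals": list(config.intervals),
            "total_pairs": len(pairs),
        }
    )
    return ds
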