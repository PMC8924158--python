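"""Artificial-language stimuli: lexicons, constrained streams, test words, schedules.

The stimulus material is a miniature artificial language of four trisyllabic
pseudo-words built from 12 consonant--vowel syllables.  Continuous streams are
produced by constrained concatenation (no immediate repetition, no repeated
pairwise alternation), so that within-word syllable transitions are fully
predictive while between-word transitions are close to uniform.  Everything in
this module is symbolic: a stream is a timed sequence of syllable tokens, not
an audio waveform.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SYLLABLE_DURATION",
    "WORD_DURATION",
    "CONDITIONS",
    "Lexicon",
    "SymbolStream",
    "TPMatrix",
    "TestWord",
    "TestEvent",
    "Segment",
    "SessionSchedule",
    "StreamGenerationError",
    "build_lexicon",
    "generate_structured_stream",
    "generate_random_stream",
    "empirical_tps",
    "between_word_tp_summary",
    "part_word_counts",
    "make_test_words",
    "build_session_schedule",
    "audit_stream",
    "test_words_frame",
    "events_frame",
]

SYLLABLE_DURATION = 0.25
"""Duration of one syllable token in seconds."""

WORD_DURATION = 3 * SYLLABLE_DURATION
"""Duration of one trisyllabic word in seconds (0.75 s)."""

CONDITIONS = ("Word", "EdgeWord", "PartWord", "NonWord")

# Words per list; syllable roles are (A_i, B_i, C_i) for word i.
_WORD_TABLE: dict[str, tuple[tuple[str, str, str], ...]] = {
    "A": (("di", "na", "po"), ("lu", "ti", "va"), ("fo", "bu", "mi"), ("sa", "zo", "gu")),
    "B": (("na", "po", "lu"), ("ti", "va", "fo"), ("bu", "mi", "sa"), ("zo", "gu", "di")),
    "C": (("po", "lu", "ti"), ("va", "fo", "bu"), ("mi", "sa", "zo"), ("gu", "di", "na")),
}

# Partner word index k used to build the Edge-word (A_i B_i C_k) and the
# listed Part-word (B_i C_i A_k) of word i.  Fixed, identical across lists.
_PARTNER = (1, 2, 3, 0)

_VOWELS = set("aeiou")


class StreamGenerationError(RuntimeError):
    """Raised when constrained concatenation cannot be completed."""


def _is_cv(syllable: str) -> bool:
    return (
        len(syllable) == 2
        and syllable[0] not in _VOWELS
        and syllable[1] in _VOWELS
    )


@dataclass(frozen=True)
class Lexicon:
    """Four trisyllabic words with A/B/C syllable roles.

    Attributes
    ----------
    list_id:
        One of ``"A"``, ``"B"``, ``"C"``.
    words:
        Four ordered (A_i, B_i, C_i) syllable triplets.
    syllable_duration:
        Nominal syllable duration in seconds.
    """

    list_id: str
    words: tuple[tuple[str, str, str], ...]
    syllable_duration: float = SYLLABLE_DURATION

    def __post_init__(self) -> None:
        if len(self.words) != 4 or any(len(w) != 3 for w in self.words):
            raise ValueError("lexicon must contain exactly 4 trisyllabic words")
        syllables = [s for w in self.words for s in w]
        if len(set(syllables)) != 12:
            raise ValueError("lexicon integrity error: 12 distinct syllables required")
        bad = [s for s in syllables if not _is_cv(s)]
        if bad:
            raise ValueError(f"lexicon integrity error: non consonant-vowel syllables {bad}")

    @property
    def syllables(self) -> tuple[str, ...]:
        """All 12 syllables in word order."""
        return tuple(s for w in self.words for s in w)

    @property
    def a_syllables(self) -> tuple[str, ...]:
        return tuple(w[0] for w in self.words)

    def word_string(self, i: int) -> str:
        return "".join(self.words[i])


def build_lexicon(list_id: str) -> Lexicon:
    """Return the lexicon for stimulus list ``list_id``.

    Raises
    ------
    ValueError
        If ``list_id`` is not one of A, B, C.
    """
    try:
        words = _WORD_TABLE[list_id]
    except KeyError:
        raise ValueError(
            f"unknown list_id {list_id!r}; valid ids are {sorted(_WORD_TABLE)}"
        ) from None
    return Lexicon(list_id=list_id, words=words)


@dataclass(frozen=True)
class SymbolStream:
    """A timed sequence of syllable tokens.

    ``word_index`` and ``within_word_position`` are present for structured
    streams only (``None`` for random streams).
    """

    tokens: tuple[str, ...]
    onsets: np.ndarray
    duration: float
    word_index: np.ndarray | None = None
    within_word_position: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.tokens)
        if len(self.onsets) != n:
            raise ValueError("onsets and tokens length mismatch")
        if n > 1:
            steps = np.diff(self.onsets)
            if not np.allclose(steps, SYLLABLE_DURATION):
                raise ValueError("onsets must advance in constant syllable steps")
        if n != round(self.duration / SYLLABLE_DURATION):
            raise ValueError("token count inconsistent with duration")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def is_structured(self) -> bool:
        return self.word_index is not None

    def word_sequence(self) -> np.ndarray:
        """Word indices in presentation order (structured streams only)."""
        if self.word_index is None:
            raise ValueError("stream carries no word annotations")
        first = self.within_word_position == 1
        return self.word_index[first]

    def word_onsets(self) -> np.ndarray:
        """Onsets (s) of the first syllable of each word."""
        if self.within_word_position is None:
            raise ValueError("stream carries no word annotations")
        return self.onsets[self.within_word_position == 1]


@dataclass(frozen=True)
class TPMatrix:
    """Adjacent-pair transition counts and probabilities.

    ``probabilities`` are row-normalized by outgoing-transition totals; rows
    with no outgoing transitions are flagged in ``zero_rows`` and left at 0.
    ``row_occurrences`` holds total token occurrences per label (including a
    stream-final token that has no successor), which supports the
    occurrence-normalized estimate used in the stream audits.
    """

    labels: tuple
    counts: np.ndarray
    probabilities: np.ndarray
    row_occurrences: np.ndarray
    zero_rows: tuple[int, ...] = ()

    def occurrence_probabilities(self) -> np.ndarray:
        """Transition probabilities with token occurrences as denominator.

        For a finite stream the row of the final token sums to slightly less
        than 1, which is exactly how the printed between-word TP statistics
        (mean 0.332 for 180 s; 0.325 pooled over the short streams) arise.
        """
        denom = np.where(self.row_occurrences > 0, self.row_occurrences, 1)
        return self.counts / denom[:, None]


@dataclass(frozen=True)
class TestWord:
    """An isolated test triplet with its condition label."""

    syllables: tuple[str, str, str]
    condition: str
    source_word_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")

    @property
    def label(self) -> str:
        return "".join(self.syllables)


def make_test_words(lexicon: Lexicon) -> tuple[TestWord, ...]:
    """Build the 16 test triplets (4 per condition) for a lexicon.

    Conditions: Word = A_iB_iC_i, EdgeWord = A_iB_iC_k, PartWord = B_iC_iA_k,
    NonWord = B_iC_iA_i, with the partner index k fixed per word.
    """
    out: list[TestWord] = []
    for i, (a, b, c) in enumerate(lexicon.words):
        k = _PARTNER[i]
        ck = lexicon.words[k][2]
        ak = lexicon.words[k][0]
        out.append(TestWord((a, b, c), "Word", (i,)))
        out.append(TestWord((a, b, ck), "EdgeWord", (i, k)))
        out.append(TestWord((b, c, ak), "PartWord", (i, k)))
        out.append(TestWord((b, c, a), "NonWord", (i,)))
    return tuple(out)


# ---------------------------------------------------------------------------
# Stream generation
# ---------------------------------------------------------------------------

_MAX_RESTARTS = 10_000


def _concatenate(
    n_items: int,
    n_symbols: int,
    quotas: list[int] | None,
    rng: np.random.Generator,
) -> list[int]:
    """Sample a sequence under the no-repeat / no-double-alternation rules.

    ``quotas`` enforces exact per-symbol counts when given.  Among the
    candidates that satisfy the constraints, the sampler prefers (with random
    tie-breaking) the successor whose transition from the previous symbol has
    been used least, which keeps the empirical transition counts near-uniform
    — this is what produces the tight between-transition spread of the
    published streams.  Dead ends trigger a restart; after ``_MAX_RESTARTS``
    failures a :class:`StreamGenerationError` is raised (reseeding is the
    suggested remedy).
    """
    seq, _ = _concatenate_with_state(
        n_items, n_symbols, quotas, rng, tolerance=0, init_trans=None
    )
    return seq


def _concatenate_with_state(
    n_items: int,
    n_symbols: int,
    quotas: list[int] | None,
    rng: np.random.Generator,
    tolerance: int = 0,
    init_trans: np.ndarray | None = None,
) -> tuple[list[int], np.ndarray]:
    """Constrained sampler returning the sequence and its balance state.

    ``init_trans`` seeds the transition-count matrix used for balancing (its
    entries are *not* part of the returned within-sequence counts), which lets
    a series of streams be balanced jointly.  ``tolerance`` relaxes the
    balance preference to transitions within ``tolerance`` of the least-used.
    """
    for _ in range(_MAX_RESTARTS):
        remaining = list(quotas) if quotas is not None else None
        trans = (
            init_trans.copy()
            if init_trans is not None
            else np.zeros((n_symbols, n_symbols), dtype=int)
        )
        seq: list[int] = []
        dead = False
        for _pos in range(n_items):
            allowed = []
            for s in range(n_symbols):
                if remaining is not None and remaining[s] == 0:
                    continue
                if seq and seq[-1] == s:
                    continue  # X X
                if len(seq) >= 3 and seq[-2] == s and seq[-3] == seq[-1]:
                    continue  # X Y X Y
                allowed.append(s)
            if not allowed:
                dead = True
                break
            if seq:
                prev = seq[-1]
                lo = min(trans[prev, s] for s in allowed)
                allowed = [s for s in allowed if trans[prev, s] <= lo + tolerance]
            s = allowed[rng.integers(len(allowed))]
            if seq:
                trans[seq[-1], s] += 1
            seq.append(s)
            if remaining is not None:
                remaining[s] -= 1
        if not dead:
            return seq, trans
    raise StreamGenerationError(
        "could not satisfy concatenation constraints after "
        f"{_MAX_RESTARTS} restarts; try a different seed"
    )


def generate_structured_stream(
    lexicon: Lexicon, duration: float, seed: int = 0
) -> SymbolStream:
    """Generate a structured stream of ``duration`` seconds.

    The word sequence is exactly balanced (each word appears
    ``duration / 0.75 / 4`` times), never repeats a word immediately and never
    contains a double alternation W_k W_j W_k W_j.

    Parameters
    ----------
    lexicon:
        Source lexicon.
    duration:
        Stream length in seconds; must be a positive multiple of 0.75 s whose
        word count is divisible by 4.
    seed:
        Seed for the concatenation sampler; output is deterministic given it.
    """
    n_words_f = duration / WORD_DURATION
    n_words = round(n_words_f)
    if duration <= 0 or abs(n_words_f - n_words) > 1e-9:
        raise ValueError(f"duration {duration} s is not a positive multiple of 0.75 s")
    if n_words % 4 != 0:
        raise ValueError(
            f"word count {n_words} not divisible by 4; balanced design impossible"
        )
    rng = np.random.default_rng(seed)
    quota = n_words // 4
    seq = _concatenate(n_words, 4, [quota] * 4, rng)
    return _stream_from_word_seq(lexicon, seq, duration)


def _stream_from_word_seq(
    lexicon: Lexicon, seq: Sequence[int], duration: float
) -> SymbolStream:
    tokens: list[str] = []
    widx: list[int] = []
    wpos: list[int] = []
    for w in seq:
        for p, syll in enumerate(lexicon.words[w], start=1):
            tokens.append(syll)
            widx.append(w)
            wpos.append(p)
    onsets = np.arange(len(tokens)) * SYLLABLE_DURATION
    return SymbolStream(
        tokens=tuple(tokens),
        onsets=onsets,
        duration=duration,
        word_index=np.asarray(widx),
        within_word_position=np.asarray(wpos),
    )


def generate_structured_stream_series(
    lexicon: Lexicon, n_streams: int, duration_each: float, seed: int = 0
) -> tuple[SymbolStream, ...]:
    """Generate ``n_streams`` structured streams balanced as a set.

    Each stream individually satisfies the concatenation constraints and the
    exact word balance, while the transition-balance state carries over from
    one stream to the next so that the *pooled* transition counts stay tight
    (e.g. every part-word 24--28 occurrences over eight 30 s streams).
    """
    n_words_f = duration_each / WORD_DURATION
    n_words = round(n_words_f)
    if duration_each <= 0 or abs(n_words_f - n_words) > 1e-9:
        raise ValueError(f"duration {duration_each} s is not a positive multiple of 0.75 s")
    if n_words % 4 != 0:
        raise ValueError(f"word count {n_words} not divisible by 4")
    rng = np.random.default_rng(seed)
    quota = n_words // 4
    trans = np.zeros((4, 4), dtype=int)
    streams: list[SymbolStream] = []
    for _ in range(n_streams):
        seq, trans = _concatenate_with_state(
            n_words, 4, [quota] * 4, rng, tolerance=1, init_trans=trans
        )
        streams.append(_stream_from_word_seq(lexicon, seq, duration_each))
    return tuple(streams)


def generate_random_stream(
    lexicon: Lexicon, duration: float, seed: int = 0
) -> SymbolStream:
    """Generate a random syllable stream with near-uniform transitions.

    The same 12 syllables are concatenated with the only restrictions that a
    syllable never repeats immediately and no two syllables alternate more
    than two times.
    """
    n_f = duration / SYLLABLE_DURATION
    n = round(n_f)
    if duration <= 0 or abs(n_f - n) > 1e-9:
        raise ValueError(f"duration {duration} s is not a positive multiple of 0.25 s")
    rng = np.random.default_rng(seed)
    seq = _concatenate(n, 12, None, rng)
    sylls = lexicon.syllables
    tokens = tuple(sylls[s] for s in seq)
    onsets = np.arange(n) * SYLLABLE_DURATION
    return SymbolStream(tokens=tokens, onsets=onsets, duration=duration)


# ---------------------------------------------------------------------------
# Transition statistics
# ---------------------------------------------------------------------------


def _tp_from_sequence(seq: Sequence, labels: Sequence) -> TPMatrix:
    index = {lab: i for i, lab in enumerate(labels)}
    k = len(labels)
    counts = np.zeros((k, k), dtype=int)
    occ = np.zeros(k, dtype=int)
    for lab in seq:
        occ[index[lab]] += 1
    for a, b in zip(seq[:-1], seq[1:]):
        counts[index[a], index[b]] += 1
    row_sums = counts.sum(axis=1)
    probs = np.zeros_like(counts, dtype=float)
    zero_rows = []
    for i in range(k):
        if row_sums[i] > 0:
            probs[i] = counts[i] / row_sums[i]
        else:
            zero_rows.append(i)
    return TPMatrix(
        labels=tuple(labels),
        counts=counts,
        probabilities=probs,
        row_occurrences=occ,
        zero_rows=tuple(zero_rows),
    )


def empirical_tps(
    stream: SymbolStream, level: str = "syllable", lexicon: Lexicon | None = None
) -> TPMatrix:
    """Empirical transitional probabilities of a stream.

    Parameters
    ----------
    level:
        ``"syllable"`` counts adjacent syllable-token pairs; ``"word"`` counts
        adjacent word pairs and requires word annotations.
    lexicon:
        Fixes the label ordering when given; otherwise labels follow first
        appearance.
    """
    if len(stream) == 0:
        raise ValueError("cannot estimate TPs of an empty stream")
    if level == "syllable":
        labels = lexicon.syllables if lexicon is not None else tuple(dict.fromkeys(stream.tokens))
        return _tp_from_sequence(stream.tokens, labels)
    if level == "word":
        seq = stream.word_sequence()
        return _tp_from_sequence(list(seq), list(range(4)))
    raise ValueError(f"unknown level {level!r}")


def between_word_tp_summary(
    streams: SymbolStream | Iterable[SymbolStream],
) -> dict[str, float]:
    """Mean/SD/range of the 12 between-word TPs, pooled over streams.

    Counts are pooled across streams before normalization.  The denominator is
    the number of *occurrences* of the antecedent word (a stream-final word
    contributes an occurrence but no transition), matching the convention
    under which the printed stimulus statistics were computed.
    """
    if isinstance(streams, SymbolStream):
        streams = [streams]
    counts = np.zeros((4, 4), dtype=int)
    occ = np.zeros(4, dtype=int)
    for st in streams:
        tp = empirical_tps(st, level="word")
        counts += tp.counts
        occ += tp.row_occurrences
    probs = counts / np.where(occ > 0, occ, 1)[:, None]
    off = ~np.eye(4, dtype=bool)
    vals = probs[off]
    return {
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=1)),
        "min": float(vals.min()),
        "max": float(vals.max()),
    }


def part_word_counts(
    stream: SymbolStream | Iterable[SymbolStream], lexicon: Lexicon
) -> dict[str, int]:
    """Occurrences of each of the 12 possible part-words B_iC_iA_k (k != i).

    Counted by sliding a 3-syllable window over the token sequence; pooled
    when several streams are given.
    """
    if isinstance(stream, SymbolStream):
        stream = [stream]
    trigram_to_label: dict[tuple[str, str, str], str] = {}
    counts: dict[str, int] = {}
    for i, (a_i, b_i, c_i) in enumerate(lexicon.words):
        for k in range(4):
            if k == i:
                continue
            tri = (b_i, c_i, lexicon.words[k][0])
            label = "".join(tri)
            trigram_to_label[tri] = label
            counts[label] = 0
    for st in stream:
        toks = st.tokens
        for j in range(len(toks) - 2):
            lab = trigram_to_label.get((toks[j], toks[j + 1], toks[j + 2]))
            if lab is not None:
                counts[lab] += 1
    return counts


# ---------------------------------------------------------------------------
# Session schedule
# ---------------------------------------------------------------------------

SEGMENT_KINDS = ("RestingState", "RandomStream", "StructuredStream", "TestBlock", "Silence")

ISI_RANGE = (2.0, 2.5)
PRE_TEST_SILENCE = 2.5


@dataclass(frozen=True)
class TestEvent:
    """One isolated test-word presentation within a test block."""

    onset_s: float
    test_word: TestWord
    block: int


@dataclass(frozen=True)
class Segment:
    kind: str
    start_s: float
    duration_s: float
    payload: SymbolStream | tuple[TestEvent, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise ValueError(f"unknown segment kind {self.kind!r}")


@dataclass(frozen=True)
class SessionSchedule:
    """Ordered segments of one recording session."""

    lexicon: Lexicon
    segments: tuple[Segment, ...]
    seed: int

    @property
    def total_duration(self) -> float:
        last = self.segments[-1]
        return last.start_s + last.duration_s

    @property
    def test_events(self) -> tuple[TestEvent, ...]:
        out: list[TestEvent] = []
        for seg in self.segments:
            if seg.kind == "TestBlock":
                out.extend(seg.payload)
        return tuple(out)

    def segments_of(self, kind: str) -> tuple[Segment, ...]:
        return tuple(s for s in self.segments if s.kind == kind)


def build_session_schedule(lexicon: Lexicon, seed: int = 0) -> SessionSchedule:
    """Build the full session protocol.

    Order: 60 s resting state, 120 s random stream, 180 s structured stream,
    then 8 series of [30 s structured stream, 2.5 s silence, 16 test words
    with ISI uniform in [2, 2.5] s], then 120 s random stream and 60 s resting
    state.  Every block presents all 16 test words in random order, so the
    session carries 128 test events.
    """
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    def sub_seed() -> int:
        return int(rng.integers(2**31))

    words = make_test_words(lexicon)
    segments: list[Segment] = []
    t = 0.0

    def add(kind: str, duration: float, payload=None) -> None:
        nonlocal t
        segments.append(Segment(kind, t, duration, payload))
        t += duration

    add("RestingState", 60.0)
    add("RandomStream", 120.0, generate_random_stream(lexicon, 120.0, sub_seed()))
    add("StructuredStream", 180.0, generate_structured_stream(lexicon, 180.0, sub_seed()))
    shorts = generate_structured_stream_series(lexicon, 8, 30.0, sub_seed())
    for block in range(1, 9):
        add("StructuredStream", 30.0, shorts[block - 1])
        add("Silence", PRE_TEST_SILENCE)
        order = rng.permutation(16)
        events: list[TestEvent] = []
        onset = t
        for j in order:
            events.append(TestEvent(onset_s=onset, test_word=words[j], block=block))
            isi = rng.uniform(*ISI_RANGE)
            onset += WORD_DURATION + isi
        add("TestBlock", onset - t, tuple(events))
    add("RandomStream", 120.0, generate_random_stream(lexicon, 120.0, sub_seed()))
    add("RestingState", 60.0)
    return SessionSchedule(lexicon=lexicon, segments=tuple(segments), seed=seed)


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------


def test_words_frame(lexicon: Lexicon) -> pd.DataFrame:
    """Test words as a long table (word_index, position, syllable, condition)."""
    rows = []
    for tw in make_test_words(lexicon):
        for pos, syll in enumerate(tw.syllables, start=1):
            rows.append(
                {
                    "word_index": tw.source_word_indices[0],
                    "position": pos,
                    "syllable": syll,
                    "condition": tw.condition,
                }
            )
    return pd.DataFrame(rows)


def events_frame(schedule: SessionSchedule) -> pd.DataFrame:
    """Flatten a schedule into the events sidecar table.

    One row per segment (kind ``segment``) and one row per syllable token
    (kind ``syllable``); test-word syllables additionally carry the condition
    label and block index on each of their three tokens.
    """
    rows = []
    for seg in schedule.segments:
        rows.append(
            {
                "onset_s": seg.start_s,
                "duration_s": seg.duration_s,
                "kind": "segment",
                "token": "",
                "segment_kind": seg.kind,
                "word_index": -1,
                "position": 0,
                "condition": "",
                "block": 0,
            }
        )
        if seg.kind in ("RandomStream", "StructuredStream"):
            st: SymbolStream = seg.payload
            for j, tok in enumerate(st.tokens):
                rows.append(
                    {
                        "onset_s": seg.start_s + st.onsets[j],
                        "duration_s": SYLLABLE_DURATION,
                        "kind": "syllable",
                        "token": tok,
                        "segment_kind": seg.kind,
                        "word_index": int(st.word_index[j]) if st.is_structured else -1,
                        "position": int(st.within_word_position[j]) if st.is_structured else 0,
                        "condition": "",
                        "block": 0,
                    }
                )
        elif seg.kind == "TestBlock":
            for ev in seg.payload:
                for pos, syll in enumerate(ev.test_word.syllables, start=1):
                    rows.append(
                        {
                            "onset_s": ev.onset_s + (pos - 1) * SYLLABLE_DURATION,
                            "duration_s": SYLLABLE_DURATION,
                            "kind": "syllable",
                            "token": syll,
                            "segment_kind": "TestBlock",
                            "word_index": ev.test_word.source_word_indices[0],
                            "position": pos,
                            "condition": ev.test_word.condition,
                            "block": ev.block,
                        }
                    )
    df = pd.DataFrame(rows)
    # microsecond rounding keeps the TSV sidecar byte-stable across IO round trips
    df["onset_s"] = df["onset_s"].round(6)
    df["duration_s"] = df["duration_s"].round(6)
    return df.sort_values("onset_s", kind="stable").reset_index(drop=True)


def audit_stream(
    streams: SymbolStream | Iterable[SymbolStream], lexicon: Lexicon
) -> dict:
    """Word counts, part-word counts and between-word TP summary.

    Streams whose minimum part-word count falls outside the typical emergent
    range are flagged (``part_word_flag``) but never rejected.
    """
    if isinstance(streams, SymbolStream):
        streams = [streams]
    streams = list(streams)
    word_counts = np.zeros(4, dtype=int)
    for st in streams:
        seq = st.word_sequence()
        for w in seq:
            word_counts[w] += 1
    pw = part_word_counts(streams, lexicon)
    tp = between_word_tp_summary(streams)
    pw_min, pw_max = min(pw.values()), max(pw.values())
    n_words = int(word_counts.sum())
    # Emergent range scales with stream length: ~ [0.9, 1.05] x mean transitions/cell.
    mean_per_cell = (n_words - len(streams)) / 12
    return {
        "word_counts": {lexicon.word_string(i): int(word_counts[i]) for i in range(4)},
        "part_word_counts": pw,
        "part_word_min": pw_min,
        "part_word_max": pw_max,
        "part_word_flag": bool(pw_min < 0.85 * mean_per_cell),
        "tp_mean": tp["mean"],
        "tp_sd": tp["sd"],
        "tp_min": tp["min"],
        "tp_max": tp["max"],
    }
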