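"""Encoding and decoding of queries and answers.

Queries are Morse-coded digit/operator strings rendered as timed pulse
trains; answers come back either as gaze-Morse (left = dot, right = dash),
as counted left-right eye-movement pairs, or as facial-muscle contraction
codes (zygomatic = yes/up, corrugator = no/down).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence, Union

__all__ = [
    "Symbol",
    "Direction",
    "CodeKind",
    "Muscle",
    "MuscleMeaning",
    "TimingParams",
    "MorseSequence",
    "EyeDirectionSequence",
    "MuscleCode",
    "Pulse",
    "MORSE_TABLE",
    "UNRECOGNIZED",
    "MALFORMED",
    "encode_morse",
    "pulse_train",
    "train_duration_ms",
    "decode_gaze_morse",
    "decode_lr_count",
    "encode_answer",
    "muscle_code_for_word",
]


class Symbol(str, Enum):
    DOT = "."
    DASH = "-"


class Direction(str, Enum):
    L = "L"
    R = "R"


class CodeKind(str, Enum):
    MORSE_GAZE = "MORSE_GAZE"
    LR_COUNT = "LR_COUNT"


class Muscle(str, Enum):
    ZYGOMATIC = "ZYGOMATIC"
    CORRUGATOR = "CORRUGATOR"


class MuscleMeaning(str, Enum):
    YES = "YES"
    NO = "NO"
    UP = "UP"
    DOWN = "DOWN"
    MIXED = "MIXED"
    COUNT = "COUNT"


#: International Morse code restricted to the task alphabet: the ten digits
#: plus 'P' (plus) and 'M' (minus).
MORSE_TABLE: dict[str, str] = {
    "0": "-----",
    "1": ".----",
    "2": "..---",
    "3": "...--",
    "4": "....-",
    "5": ".....",
    "6": "-....",
    "7": "--...",
    "8": "---..",
    "9": "----.",
    "P": ".--.",
    "M": "--",
}

_INVERSE_MORSE: dict[str, str] = {v: k for k, v in MORSE_TABLE.items()}

#: Sentinel returned by :func:`decode_gaze_morse` for sequences that match no
#: character of the task alphabet.
UNRECOGNIZED = "unrecognized"
#: Sentinel returned by :func:`decode_lr_count` for non-alternating or
#: incomplete left-right sequences.
MALFORMED = "malformed"

_PLUS_TOKENS = {"plus", "p", "+"}
_MINUS_TOKENS = {"minus", "m", "-"}


@dataclass(frozen=True)
class TimingParams:
    """Stimulus/answer timing constants (milliseconds unless suffixed)."""

    dot_ms: float = 300.0
    dash_ms: float = 900.0
    intra_gap_ms: float = 300.0
    char_gap_ms: float = 3000.0
    answer_window_s: float = 20.0

    def __post_init__(self) -> None:
        for name in ("dot_ms", "dash_ms", "intra_gap_ms", "char_gap_ms", "answer_window_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.dash_ms <= self.dot_ms:
            raise ValueError("dash_ms must exceed dot_ms")


@dataclass(frozen=True)
class MorseSequence:
    """Ordered characters, each a tuple of DOT/DASH symbols."""

    characters: tuple[tuple[Symbol, ...], ...]
    source_text: str = ""

    def __post_init__(self) -> None:
        for char in self.characters:
            if len(char) == 0:
                raise ValueError("every character must map to a non-empty symbol list")

    def __len__(self) -> int:
        return len(self.characters)

    def as_strings(self) -> tuple[str, ...]:
        return tuple("".join(s.value for s in char) for char in self.characters)


@dataclass(frozen=True)
class EyeDirectionSequence:
    """An ordered left/right gaze sequence under a declared answer code."""

    directions: tuple[Direction, ...]
    code_kind: CodeKind = CodeKind.LR_COUNT

    def __str__(self) -> str:
        return "".join(d.value for d in self.directions)

    @classmethod
    def from_string(cls, s: str, code_kind: CodeKind = CodeKind.LR_COUNT) -> "EyeDirectionSequence":
        return cls(tuple(Direction(c) for c in s), code_kind)


@dataclass(frozen=True)
class MuscleCode:
    """A facial-muscle answer: which muscle, how many contractions, meaning.

    The MIXED code is one corrugator contraction followed by one zygomatic
    contraction and is represented with ``muscle`` = CORRUGATOR (the leading
    muscle) and ``contraction_count`` = 2.
    """

    muscle: Muscle
    contraction_count: int
    meaning: MuscleMeaning

    def __post_init__(self) -> None:
        m, n, mean = self.muscle, self.contraction_count, self.meaning
        if n < 1:
            raise ValueError("contraction_count must be >= 1")
        constraints = {
            MuscleMeaning.YES: (Muscle.ZYGOMATIC, 2),
            MuscleMeaning.NO: (Muscle.CORRUGATOR, 2),
            MuscleMeaning.UP: (Muscle.ZYGOMATIC, 2),
            MuscleMeaning.DOWN: (Muscle.CORRUGATOR, 2),
            MuscleMeaning.MIXED: (Muscle.CORRUGATOR, 2),
        }
        if mean in constraints and (m, n) != constraints[mean]:
            want_m, want_n = constraints[mean]
            raise ValueError(
                f"{mean.value} requires {want_m.value} x{want_n}, got {m.value} x{n}"
            )


def muscle_code_for_word(word: str) -> MuscleCode:
    """Map a semantic-task word (up/down/mixed) or yes/no to its muscle code."""
    table = {
        "yes": MuscleCode(Muscle.ZYGOMATIC, 2, MuscleMeaning.YES),
        "no": MuscleCode(Muscle.CORRUGATOR, 2, MuscleMeaning.NO),
        "up": MuscleCode(Muscle.ZYGOMATIC, 2, MuscleMeaning.UP),
        "down": MuscleCode(Muscle.CORRUGATOR, 2, MuscleMeaning.DOWN),
        "mixed": MuscleCode(Muscle.CORRUGATOR, 2, MuscleMeaning.MIXED),
    }
    try:
        return table[word.lower()]
    except KeyError:
        raise ValueError(f"no muscle code for word {word!r}") from None


def encode_morse(text: str) -> MorseSequence:
    """Encode a problem string (digits plus 'plus'/'minus') as Morse.

    Tokens are whitespace-separated; a token is either a run of digits
    (one Morse character per digit) or a plus/minus word or letter.

    Raises
    ------
    ValueError
        If the text contains an unsupported character; the message names it.
    """
    characters: list[tuple[Symbol, ...]] = []
    for token in text.split():
        low = token.lower()
        if low in _PLUS_TOKENS:
            characters.append(_char_symbols("P"))
        elif low in _MINUS_TOKENS:
            characters.append(_char_symbols("M"))
        else:
            for ch in token:
                if ch not in MORSE_TABLE:
                    raise ValueError(f"unsupported character {ch!r} in {text!r}")
                characters.append(_char_symbols(ch))
    return MorseSequence(tuple(characters), source_text=text)


def _char_symbols(ch: str) -> tuple[Symbol, ...]:
    return tuple(Symbol(c) for c in MORSE_TABLE[ch])


@dataclass(frozen=True)
class Pulse:
    onset_ms: float
    duration_ms: float
    symbol: Symbol


def pulse_train(seq: MorseSequence, timing: TimingParams = TimingParams()) -> list[Pulse]:
    """Lay out a Morse sequence as timed pulses.

    Symbols within a character are separated by ``intra_gap_ms``; characters
    by ``char_gap_ms``. The train starts at t = 0 and ends at the offset of
    the last pulse (no trailing gap).
    """
    pulses: list[Pulse] = []
    t = 0.0
    for ci, char in enumerate(seq.characters):
        if ci > 0:
            t += timing.char_gap_ms
        for si, sym in enumerate(char):
            if si > 0:
                t += timing.intra_gap_ms
            dur = timing.dot_ms if sym is Symbol.DOT else timing.dash_ms
            pulses.append(Pulse(onset_ms=t, duration_ms=dur, symbol=sym))
            t += dur
    return pulses


def train_duration_ms(pulses: Sequence[Pulse]) -> float:
    """Total duration from t = 0 to the offset of the last pulse."""
    if not pulses:
        return 0.0
    last = pulses[-1]
    return last.onset_ms + last.duration_ms


def decode_gaze_morse(dirs: EyeDirectionSequence) -> str:
    """Decode a gaze-Morse answer (L = dot, R = dash) to a task character.

    Sequences that decode to anything outside the 0-9/P/M alphabet return
    :data:`UNRECOGNIZED` — a detection-failure signal, not an exception.
    """
    if dirs.code_kind is not CodeKind.MORSE_GAZE:
        raise ValueError("decode_gaze_morse requires code_kind MORSE_GAZE")
    pattern = "".join("." if d is Direction.L else "-" for d in dirs.directions)
    return _INVERSE_MORSE.get(pattern, UNRECOGNIZED)


def decode_lr_count(dirs: EyeDirectionSequence) -> Union[int, str]:
    """Count complete left-right pairs (LR = 1, LRLR = 2, ...).

    Anything other than a strict L-first alternation of complete pairs
    returns :data:`MALFORMED`.
    """
    if dirs.code_kind is not CodeKind.LR_COUNT:
        raise ValueError("decode_lr_count requires code_kind LR_COUNT")
    seq = dirs.directions
    if not seq or len(seq) % 2 != 0:
        return MALFORMED
    for i, d in enumerate(seq):
        expected = Direction.L if i % 2 == 0 else Direction.R
        if d is not expected:
            return MALFORMED
    return len(seq) // 2


def encode_answer(value: int, code_kind: CodeKind) -> EyeDirectionSequence:
    """Render an integer answer as an eye-direction sequence.

    LR_COUNT: ``value`` left-right pairs (value >= 1). MORSE_GAZE: the digit's
    Morse pattern with dot = L, dash = R (value in 0-9).
    """
    if code_kind is CodeKind.LR_COUNT:
        if value < 1:
            raise ValueError(f"LR_COUNT answers must be >= 1, got {value}")
        dirs = (Direction.L, Direction.R) * value
        return EyeDirectionSequence(dirs, CodeKind.LR_COUNT)
    if code_kind is CodeKind.MORSE_GAZE:
        if not 0 <= value <= 9:
            raise ValueError(f"MORSE_GAZE answers must be digits 0-9, got {value}")
        pattern = MORSE_TABLE[str(value)]
        dirs = tuple(Direction.L if c == "." else Direction.R for c in pattern)
        return EyeDirectionSequence(dirs, CodeKind.MORSE_GAZE)
    raise ValueError(f"unknown code kind {code_kind}")
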