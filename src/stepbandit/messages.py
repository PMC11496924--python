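"""Feedback and motivational message banks.

The daily intervention draws from two banks of short bilingual (English /
Spanish) text messages:

* **feedback** messages report on yesterday's step count, in 5 categories
  (code 0 is the explicit "no feedback message" option);
* **motivational** messages are grounded in the COM-B behaviour-change
  framework — capability, motivation, opportunity — plus a "no message"
  option (4 codes total);
* a weekly **mood** self-monitoring message goes to every arm.

The decision policies personalise only the *category* and *timing* of a
message; the specific text within a category is drawn uniformly at random.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

FEEDBACK = "feedback"
MOTIVATION = "motivation"
MOOD = "mood"
KINDS = (FEEDBACK, MOTIVATION, MOOD)
LANGUAGES = ("en", "es")

#: Feedback categories: code 0 is the explicit "no feedback message" option.
FEEDBACK_CATEGORIES = {
    0: "none",
    1: "goal_attainment",
    2: "steps_walked",
    3: "relative_to_goal",
    4: "steps_plus_encouragement",
}

#: Motivational categories follow COM-B; code 0 is the "no message" option.
MOTIVATION_CATEGORIES = {
    0: "none",
    1: "capability",
    2: "motivation",
    3: "opportunity",
}

MOOD_CATEGORIES = {0: "mood_check"}

CATEGORY_CODES = {
    FEEDBACK: FEEDBACK_CATEGORIES,
    MOTIVATION: MOTIVATION_CATEGORIES,
    MOOD: MOOD_CATEGORIES,
}

#: Each motivational category carries at most this many texts per language.
MAX_TEXTS_PER_CELL = 18

_PLACEHOLDER = re.compile(r"\{(\w+)\}")

_CSV_COLUMNS = ("id", "kind", "category_code", "language", "text")


class BankParseError(ValueError):
    """A bank file is malformed (bad format, missing columns/keys)."""


class BankValidationError(ValueError):
    """A parsed bank violates the coverage or size invariants."""

    def __init__(self, missing: Sequence[tuple] = (), oversized: Sequence[tuple] = ()):
        self.missing = list(missing)
        self.oversized = list(oversized)
        parts = []
        if self.missing:
            parts.append(f"missing (kind, category, language) cells: {self.missing}")
        if self.oversized:
            parts.append(
                f"cells exceeding {MAX_TEXTS_PER_CELL} texts: {self.oversized}"
            )
        super().__init__("; ".join(parts) or "invalid bank")


class RenderError(KeyError):
    """A template placeholder has no value at render time."""


class TemplateLookupError(LookupError):
    """No template matches the requested (kind, category, language)."""


@dataclass(frozen=True)
class MessageTemplate:
    """One concrete text with its category coordinates.

    ``text`` may contain ``{steps}`` / ``{goal}`` placeholders that are
    resolved by :func:`render_message`.
    """

    id: str
    kind: str
    category_code: int
    language: str
    text: str

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.category_code not in CATEGORY_CODES[self.kind]:
            raise ValueError(
                f"category code {self.category_code} invalid for kind {self.kind!r}"
            )
        if self.language not in LANGUAGES:
            raise ValueError(f"unknown language {self.language!r}")
        if not self.text:
            raise ValueError("template text must be non-empty")

    @property
    def placeholders(self) -> tuple[str, ...]:
        return tuple(_PLACEHOLDER.findall(self.text))


def sentinel_template(kind: str, language: str) -> MessageTemplate:
    """The explicit "no message" template for category code 0.

    Decision logs record every decision, including the choice to stay
    silent, so silence is a first-class template rather than a None.
    """
    text = "(no message)" if language == "en" else "(sin mensaje)"
    return MessageTemplate(
        id=f"{kind}-none-{language}",
        kind=kind,
        category_code=0,
        language=language,
        text=text,
    )


@dataclass(frozen=True)
class MessageBank:
    """A validated collection of message templates."""

    templates: tuple[MessageTemplate, ...]
    version: str = "1"

    def validate(self) -> None:
        """Check coverage and per-cell size invariants.

        Every (kind, non-zero category, language) cell for the feedback and
        motivational banks must hold at least one template; motivational
        cells hold at most :data:`MAX_TEXTS_PER_CELL` texts.
        """
        counts: dict[tuple, int] = {}
        for t in self.templates:
            counts[(t.kind, t.category_code, t.language)] = (
                counts.get((t.kind, t.category_code, t.language), 0) + 1
            )
        missing = []
        for kind in (FEEDBACK, MOTIVATION):
            for code in CATEGORY_CODES[kind]:
                if code == 0:
                    continue
                for lang in LANGUAGES:
                    if counts.get((kind, code, lang), 0) == 0:
                        missing.append((kind, code, lang))
        oversized = [
            cell
            for cell, n in counts.items()
            if cell[0] == MOTIVATION and n > MAX_TEXTS_PER_CELL
        ]
        if missing or oversized:
            raise BankValidationError(missing=missing, oversized=oversized)

    def select(
        self, kind: str, category_code: int, language: str
    ) -> tuple[MessageTemplate, ...]:
        return tuple(
            t
            for t in self.templates
            if t.kind == kind
            and t.category_code == category_code
            and t.language == language
        )


def _record_to_template(rec: dict, where: str) -> MessageTemplate:
    try:
        return MessageTemplate(
            id=str(rec["id"]),
            kind=str(rec["kind"]),
            category_code=int(rec["category_code"]),
            language=str(rec["language"]),
            text=str(rec["text"]),
        )
    except KeyError as exc:
        raise BankParseError(f"{where}: missing key {exc}") from exc
    except (TypeError, ValueError) as exc:
        raise BankParseError(f"{where}: {exc}") from exc


def load_bank(path: str | Path, format: str | None = None) -> MessageBank:
    """Load and validate a message bank from JSON or CSV.

    JSON banks are either a list of template records or an object with
    ``templates`` (and optionally ``version``). CSV banks carry the columns
    ``id, kind, category_code, language, text``.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt not in ("json", "csv"):
        raise BankParseError(f"unsupported bank format {fmt!r}")
    version = "1"
    templates: list[MessageTemplate] = []
    if fmt == "json":
        try:
            payload = json.loads(path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise BankParseError(f"{path}: invalid JSON ({exc})") from exc
        if isinstance(payload, dict):
            version = str(payload.get("version", "1"))
            records = payload.get("templates")
            if records is None:
                raise BankParseError(f"{path}: missing 'templates' key")
        else:
            records = payload
        for i, rec in enumerate(records):
            templates.append(_record_to_template(rec, f"{path} record {i}"))
    else:
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            got = tuple(reader.fieldnames or ())
            missing_cols = [c for c in _CSV_COLUMNS if c not in got]
            if missing_cols:
                raise BankParseError(f"{path}: missing columns {missing_cols}")
            for i, rec in enumerate(reader):
                templates.append(_record_to_template(rec, f"{path} row {i + 2}"))
    bank = MessageBank(templates=tuple(templates), version=version)
    bank.validate()
    return bank


def write_bank(bank: MessageBank, path: str | Path, format: str | None = None) -> Path:
    """Serialise a bank to JSON or CSV (UTF-8); inverse of :func:`load_bank`."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "json":
        payload = {
            "version": bank.version,
            "templates": [
                {
                    "id": t.id,
                    "kind": t.kind,
                    "category_code": t.category_code,
                    "language": t.language,
                    "text": t.text,
                }
                for t in bank.templates
            ],
        }
        path.write_text(
            json.dumps(payload, ensure_ascii=False, indent=1), encoding="utf-8"
        )
    elif fmt == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(_CSV_COLUMNS)
            for t in bank.templates:
                writer.writerow([t.id, t.kind, t.category_code, t.language, t.text])
    else:
        raise BankParseError(f"unsupported bank format {fmt!r}")
    return path


def render_message(template: MessageTemplate, context: dict | None = None, **values) -> str:
    """Resolve a template's placeholders against concrete values.

    Raises :class:`RenderError` naming the first placeholder without a value.
    """
    ctx = dict(context or {})
    ctx.update(values)

    def _sub(match: re.Match) -> str:
        key = match.group(1)
        if key not in ctx:
            raise RenderError(key)
        return str(ctx[key])

    return _PLACEHOLDER.sub(_sub, template.text)


def sample_template(
    bank: MessageBank,
    kind: str,
    category_code: int,
    language: str,
    rng: np.random.Generator,
) -> MessageTemplate:
    """Draw uniformly among the texts of one (kind, category, language) cell.

    Category code 0 for feedback/motivation is the "no message" decision and
    returns the sentinel template; it needs no entry in the bank file.
    """
    if kind in (FEEDBACK, MOTIVATION) and category_code == 0:
        return sentinel_template(kind, language)
    matches = bank.select(kind, category_code, language)
    if not matches:
        raise TemplateLookupError((kind, category_code, language))
    return matches[int(rng.integers(len(matches)))]


# --------------------------------------------------------------------------
# Built-in default bank
# --------------------------------------------------------------------------

_FEEDBACK_TEXTS = {
    (1, "en"): [
        "Yesterday, you reached your goal of {goal} steps!",
        "Yesterday, you did not reach your goal of {goal} steps.",
    ],
    (1, "es"): [
        "¡Ayer alcanzaste tu meta de {goal} pasos!",
        "Ayer no alcanzaste tu meta de {goal} pasos.",
    ],
    (2, "en"): [
        "Yesterday, you walked {steps} steps.",
        "You took {steps} steps yesterday.",
    ],
    (2, "es"): [
        "Ayer caminaste {steps} pasos.",
        "Diste {steps} pasos ayer.",
    ],
    (3, "en"): [
        "Yesterday, you walked more than your goal.",
        "Yesterday, you walked less than the day before.",
    ],
    (3, "es"): [
        "Ayer caminaste más que tu meta.",
        "Ayer caminaste menos que el día anterior.",
    ],
    (4, "en"): [
        "You walked {steps} steps yesterday. Great job!",
        "You walked {steps} steps yesterday. Keep it up!",
    ],
    (4, "es"): [
        "Caminaste {steps} pasos ayer. ¡Buen trabajo!",
        "Caminaste {steps} pasos ayer. ¡Sigue así!",
    ],
}

_MOTIVATION_TEXTS = {
    (1, "en"): [
        "Doing more physical activity can help reduce feelings of fatigue.",
        "A short walk can lift your mood and clear your mind.",
        "Walking regularly helps keep your blood sugar in a healthy range.",
        "Every step counts: even light activity benefits your heart.",
        "Walking during the day can improve your sleep tonight.",
        "Moving your body eases stress and builds energy.",
    ],
    (1, "es"): [
        "Hacer más actividad física puede ayudar a reducir la fatiga.",
        "Una caminata corta puede mejorar tu estado de ánimo.",
        "Caminar con regularidad ayuda a controlar el azúcar en la sangre.",
        "Cada paso cuenta: la actividad ligera también beneficia tu corazón.",
        "Caminar durante el día puede mejorar tu sueño esta noche.",
        "Mover el cuerpo alivia el estrés y da energía.",
    ],
    (2, "en"): [
        "You have made changes to improve your health before; you can do it again.",
        "You are capable of more than you think. One step at a time.",
        "Small goals add up. Today is a good day to try.",
        "Remember why you started: your health is worth it.",
        "You do not need a perfect day to take a good walk.",
        "Progress, not perfection. Every walk is a win.",
    ],
    (2, "es"): [
        "Ya has hecho cambios para mejorar tu salud; puedes hacerlo otra vez.",
        "Eres capaz de más de lo que crees. Un paso a la vez.",
        "Las metas pequeñas suman. Hoy es un buen día para intentarlo.",
        "Recuerda por qué empezaste: tu salud lo vale.",
        "No necesitas un día perfecto para dar una buena caminata.",
        "Progreso, no perfección. Cada caminata es un logro.",
    ],
    (3, "en"): [
        "Is there a local park you have been waiting to visit? Use it as a chance to get more steps!",
        "Try parking a little farther away and walking the rest.",
        "Invite a friend or family member for a walk today.",
        "Take the stairs instead of the elevator when you can.",
        "A walk after a meal is an easy way to add steps.",
        "Getting off the bus one stop early adds steps to your day.",
    ],
    (3, "es"): [
        "¿Hay un parque cerca que quieras visitar? ¡Aprovéchalo para dar más pasos!",
        "Intenta estacionarte un poco más lejos y caminar el resto.",
        "Invita a un amigo o familiar a caminar hoy.",
        "Usa las escaleras en lugar del elevador cuando puedas.",
        "Caminar después de comer es una forma fácil de sumar pasos.",
        "Bajarte del autobús una parada antes suma pasos a tu día.",
    ],
}

_MOOD_TEXTS = {
    "en": [
        "How was your mood this past week? Reply with a number from 1 (very low) to 9 (very good).",
    ],
    "es": [
        "¿Cómo estuvo tu ánimo esta semana? Responde con un número del 1 (muy bajo) al 9 (muy bueno).",
    ],
}


def default_bank() -> MessageBank:
    """The package's built-in bilingual bank (synthetic message content)."""
    templates: list[MessageTemplate] = []
    for (code, lang), texts in _FEEDBACK_TEXTS.items():
        for i, text in enumerate(texts):
            templates.append(
                MessageTemplate(f"fb-{code}-{lang}-{i}", FEEDBACK, code, lang, text)
            )
    for (code, lang), texts in _MOTIVATION_TEXTS.items():
        for i, text in enumerate(texts):
            templates.append(
                MessageTemplate(f"mo-{code}-{lang}-{i}", MOTIVATION, code, lang, text)
            )
    for lang, texts in _MOOD_TEXTS.items():
        for i, text in enumerate(texts):
            templates.append(
                MessageTemplate(f"md-0-{lang}-{i}", MOOD, 0, lang, text)
            )
    bank = MessageBank(templates=tuple(templates), version="builtin-1")
    bank.validate()
    return bank
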