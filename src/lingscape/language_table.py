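"""Phonological language table: records, derived indices, and CSV I/O.

Each language carries a point location, a residential-stability flag and a
set of phoneme-inventory and syllable-structure parameters.  From the
primitive counts several composite indices are derived:

* ``OnsCoda`` — maximal onset complexity plus maximal coda complexity (0-6);
* ``ConsHeavy`` — consonant heaviness, ``OnsCoda + CTotal/4``;
* ``CHeavyObstr`` — obstruent-based heaviness, ``OnsCoda + Obstr/3``;
* ``CHeavyLog`` — log-based heaviness, ``OnsCoda + ln(CTotal)``;
* ``ObsPct`` — percentage of obstruents among consonants;
* ``SegTot`` / ``CplusVQ`` — inventory-size sums;
* ``VowIndex`` — proportion of vowel symbols in a short transcribed
  wordlist (available only for a subset of languages).

Derived indices are always recomputed from the primitive fields; derived
columns present in an input CSV are advisory and checked, not trusted.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

TONE_CATEGORIES = ("None", "Marginal", "Simple", "Moderately Complex", "Complex")

#: Rank order of tone-system complexity: 0 = no tone, 3 = complex system
#: (more than 3 tones).  Marginal and simple systems share level 1; only a
#: complete absence of tone maps to 0.
TONE_ORDINAL_MAP = {
    "None": 0,
    "Marginal": 1,
    "Simple": 1,
    "Moderately Complex": 2,
    "Complex": 3,
}

GLOTC_CATEGORIES = (
    "No",
    "Ej",
    "Imp",
    "Res",
    "Ej & Imp",
    "Ej & Res",
    "Ej Imp & Res",
    "Imp & Res",
    "Plosives",
)

NV_PATTERNS = ("None", "Some", "All")
VLENGTH_PATTERNS = ("None", "Some", "All", "Other")

#: Length marks ignored when counting wordlist symbols, following the
#: simplified-transcription convention of the source wordlists.
DEFAULT_IGNORED_SYMBOLS = frozenset({":", "ː", "ˑ"})


def compute_ons_coda(onset: int, coda: int) -> int:
    """Sum of the onset and coda complexity indices (each 0-3), range 0-6."""
    for label, v in (("onset", onset), ("coda", coda)):
        if v not in (0, 1, 2, 3):
            raise ValidationError(f"{label} must be an integer in 0..3, got {v!r}")
    return onset + coda

def compute_cons_heavy(ons_coda: int, ctotal: int) -> float:
    """Consonant heaviness: ``ons_coda + ctotal/4``."""
    if ctotal < 1:
        raise ValidationError(f"ctotal must be >= 1, got {ctotal}")
    return ons_coda + ctotal / 4

def compute_cheavy_obstr(ons_coda: int, obstr: int) -> float:
    """Obstruent-only consonant heaviness: ``ons_coda + obstr/3``."""
    if obstr < 0:
        raise ValidationError(f"obstr must be >= 0, got {obstr}")
    return ons_coda + obstr / 3

def compute_cheavy_log(ons_coda: int, ctotal: int) -> float:
    """Log-based consonant heaviness: ``ons_coda + ln(ctotal)``.

    The natural logarithm is used; the log base is an assumption documented
    in the methods note.
    """
    if ctotal < 1:
        raise ValidationError(f"ctotal must be >= 1, got {ctotal}")
    return ons_coda + math.log(ctotal)

def compute_obs_pct(obstr: int, ctotal: int) -> float:
    """Percentage of obstruents in the consonant inventory, in [0, 100]."""
    if ctotal < 1:
        raise ValidationError(f"ctotal must be >= 1, got {ctotal}")
    if obstr < 0 or obstr > ctotal:
        raise ValidationError(f"obstr must be in 0..ctotal ({ctotal}), got {obstr}")
    return 100.0 * obstr / ctotal


def map_tone_ordinal(tone_cat: str) -> int:
    """Map a categorical tone-system label onto the 0-3 ordinal scale."""
    try:
        return TONE_ORDINAL_MAP[tone_cat]
    except KeyError:
        raise ValidationError(
            f"unknown tone category {tone_cat!r}; expected one of {TONE_CATEGORIES}"
        ) from None


def compute_vowel_index(
    wordlist: Sequence[str],
    vowel_symbols: Iterable[str],
    consonant_symbols: Iterable[str] | None = None,
    ignore_symbols: Iterable[str] = DEFAULT_IGNORED_SYMBOLS,
) -> float:
    """Proportion of vowel symbols among all classifiable symbols.

    The index is the total number of symbols representing vowels in the
    wordlist divided by the total number of symbols representing consonants
    and vowels together.  Word boundaries carry no weight and length marks
    are ignored.

    Parameters
    ----------
    wordlist:
        Non-empty sequence of transcribed words.
    vowel_symbols:
        Symbols counted as vowels.  Classification is explicit per
        transcription scheme; no orthography guessing is attempted.
    consonant_symbols:
        Optional explicit consonant set.  When given, symbols in neither
        set are excluded from the count and reported via a warning;
        when omitted every non-vowel, non-ignored symbol counts as a
        consonant.
    ignore_symbols:
        Symbols skipped entirely (length marks by default).
    """
    if not wordlist:
        raise ValidationError("wordlist is empty")
    vowels = frozenset(vowel_symbols)
    ignored = frozenset(ignore_symbols)
    consonants = frozenset(consonant_symbols) if consonant_symbols is not None else None

    n_vowel = 0
    n_total = 0
    unclassified: Counter[str] = Counter()
    for word in wordlist:
        for sym in word:
            if sym in ignored:
                continue
            if sym in vowels:
                n_vowel += 1
                n_total += 1
            elif consonants is None or sym in consonants:
                n_total += 1
            else:
                unclassified[sym] += 1
    if unclassified:
        logger.warning(
            "vowel index: %d unclassifiable symbol occurrences excluded: %s",
            sum(unclassified.values()),
            dict(unclassified),
        )
    if n_total == 0:
        raise ValidationError("wordlist contains no classifiable symbols")
    return n_vowel / n_total


@dataclass
class LanguageRecord:
    """One language: identity, location and Table-style phonological fields.

    Only primitive fields are stored; every derived index is exposed as a
    property recomputed on access, so stored and derived values can never
    disagree.
    """

    id: str
    name: str
    lon: float
    lat: float
    #: True if the speech community is judged to have been in place for at
    #: least ~300 years.
    stable: bool
    onset: int
    coda: int
    vq: int
    vtotal: int
    ctotal: int
    obstr: int
    tone_cat: str
    obs_lat: bool = False
    f_rnd_v: bool = False
    glot_c: str = "No"
    n_ejectives: int = 0
    n_implosives: int = 0
    n_glot_res: int = 0
    velar_nas: bool = False
    nv_pattern: str = "None"
    pnc: bool = False
    vlength: str = "None"
    aspirates: bool = False
    #: Wordlist vowel index in (0, 1); None when no wordlist is available.
    vow_index: float | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- derived indices -------------------------------------------------
    @property
    def ons_coda(self) -> int:
        return compute_ons_coda(self.onset, self.coda)

    @property
    def cons_heavy(self) -> float:
        return compute_cons_heavy(self.ons_coda, self.ctotal)

    @property
    def cheavy_obstr(self) -> float:
        return compute_cheavy_obstr(self.ons_coda, self.obstr)

    @property
    def cheavy_log(self) -> float:
        return compute_cheavy_log(self.ons_coda, self.ctotal)

    @property
    def obs_pct(self) -> float:
        return compute_obs_pct(self.obstr, self.ctotal)

    @property
    def seg_tot(self) -> int:
        return self.vtotal + self.ctotal

    @property
    def cplus_vq(self) -> int:
        return self.vq + self.ctotal

    @property
    def tone_ordinal(self) -> int:
        return map_tone_ordinal(self.tone_cat)

    @property
    def ejectives(self) -> bool:
        return self.n_ejectives >= 1

    @property
    def implosives(self) -> bool:
        return self.n_implosives >= 1

    @property
    def glot_res(self) -> bool:
        return self.n_glot_res >= 1

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`ValidationError` on any invariant violation."""
        if not (-180.0 <= self.lon <= 180.0):
            raise ValidationError(f"{self.id}: lon {self.lon} outside [-180, 180]")
        if not (-90.0 <= self.lat <= 90.0):
            raise ValidationError(f"{self.id}: lat {self.lat} outside [-90, 90]")
        compute_ons_coda(self.onset, self.coda)
        if self.ctotal < 1:
            raise ValidationError(f"{self.id}: ctotal must be >= 1")
        if not (0 <= self.obstr <= self.ctotal):
            raise ValidationError(f"{self.id}: obstr {self.obstr} outside 0..ctotal")
        if not (2 <= self.vq <= 20):
            raise ValidationError(f"{self.id}: vq {self.vq} outside 2..20")
        if self.vtotal < self.vq:
            raise ValidationError(f"{self.id}: vtotal {self.vtotal} < vq {self.vq}")
        if self.tone_cat not in TONE_CATEGORIES:
            raise ValidationError(f"{self.id}: unknown tone_cat {self.tone_cat!r}")
        if self.glot_c not in GLOTC_CATEGORIES:
            raise ValidationError(f"{self.id}: unknown glot_c {self.glot_c!r}")
        if self.nv_pattern not in NV_PATTERNS:
            raise ValidationError(f"{self.id}: unknown nv_pattern {self.nv_pattern!r}")
        if self.vlength not in VLENGTH_PATTERNS:
            raise ValidationError(f"{self.id}: unknown vlength {self.vlength!r}")
        for label, n in (
            ("n_ejectives", self.n_ejectives),
            ("n_implosives", self.n_implosives),
            ("n_glot_res", self.n_glot_res),
        ):
            if n < 0:
                raise ValidationError(f"{self.id}: {label} must be >= 0")
        if self.vow_index is not None and not (0.0 < self.vow_index < 1.0):
            raise ValidationError(
                f"{self.id}: vow_index {self.vow_index} outside (0, 1)"
            )


# CSV column layout: identity columns followed by the published parameter
# names; derived columns are emitted for human consumption and checked on
# input but never trusted.
_PRIMITIVE_COLUMNS = {
    "id": "id",
    "name": "name",
    "lon": "lon",
    "lat": "lat",
    "stable": "stable",
    "Onset": "onset",
    "Coda": "coda",
    "VQ": "vq",
    "VTotal": "vtotal",
    "CTotal": "ctotal",
    "Obstr": "obstr",
    "ToneCat": "tone_cat",
    "VowIndex": "vow_index",
    "ObsLat": "obs_lat",
    "FRndV": "f_rnd_v",
    "GlotC": "glot_c",
    "#Ejectives": "n_ejectives",
    "#Implosives": "n_implosives",
    "#GlotRes": "n_glot_res",
    "VelarNas": "velar_nas",
    "NVPattern": "nv_pattern",
    "PNC's": "pnc",
    "VLength": "vlength",
    "Aspirates": "aspirates",
}

_DERIVED_COLUMNS = {
    "SegTot": "seg_tot",
    "CplusVQ": "cplus_vq",
    "ObsPct": "obs_pct",
    "ToneOrdinal": "tone_ordinal",
    "OnsCoda": "ons_coda",
    "ConsHeavy": "cons_heavy",
    "CHeavyObstr": "cheavy_obstr",
    "CHeavyLog": "cheavy_log",
    "Ejectives": "ejectives",
    "Implosives": "implosives",
    "GlotRes": "glot_res",
}

_BOOL_COLUMNS = {
    "stable", "ObsLat", "FRndV", "VelarNas", "PNC's", "Aspirates",
    "Ejectives", "Implosives", "GlotRes",
}

LANGUAGE_CSV_COLUMNS = [
    "id", "name", "lon", "lat", "stable",
    "Onset", "Coda", "VQ", "VTotal", "VowIndex", "CTotal", "Obstr",
    "SegTot", "CplusVQ", "ObsPct", "ToneCat", "ToneOrdinal", "OnsCoda",
    "ConsHeavy", "CHeavyObstr", "CHeavyLog", "ObsLat", "FRndV", "GlotC",
    "Ejectives", "#Ejectives", "Implosives", "#Implosives",
    "GlotRes", "#GlotRes", "VelarNas", "NVPattern", "PNC's", "VLength",
    "Aspirates",
]


def records_to_frame(records: Sequence[LanguageRecord]) -> pd.DataFrame:
    """Full table (primitive + derived columns) as a DataFrame."""
    rows = []
    for rec in records:
        row = {}
        for col, attr in {**_PRIMITIVE_COLUMNS, **_DERIVED_COLUMNS}.items():
            value = getattr(rec, attr)
            if col in _BOOL_COLUMNS:
                value = "Yes" if value else "No"
            row[col] = value
        rows.append(row)
    return pd.DataFrame(rows, columns=LANGUAGE_CSV_COLUMNS)


def write_language_csv(records: Sequence[LanguageRecord], path) -> None:
    """Write records to ``path`` as a UTF-8 CSV with a header row."""
    records_to_frame(records).to_csv(path, index=False)


def _parse_bool(value) -> bool:
    s = str(value).strip().lower()
    if s in {"yes", "true", "1"}:
        return True
    if s in {"no", "false", "0"}:
        return False
    raise ValidationError(f"cannot parse boolean value {value!r}")


def read_language_csv(path) -> list[LanguageRecord]:
    """Read a language CSV into validated records.

    Derived-index columns present in the file are recomputed from the
    primitive fields; mismatches larger than 1e-6 are logged but never
    override the recomputed values.  Missing ``VowIndex`` cells yield
    ``None``.
    """
    # "None" is a real tone/length category; only empty cells are missing
    df = pd.read_csv(
        path, dtype={"id": str, "name": str}, keep_default_na=False, na_values=[""]
    )
    missing = [c for c in _PRIMITIVE_COLUMNS if c not in df.columns and c != "VowIndex"]
    if missing:
        raise ValidationError(f"{path}: missing mandatory columns {missing}")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValidationError(f"{path}: duplicate ids {dupes}")

    records: list[LanguageRecord] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        kwargs = {}
        for col, attr in _PRIMITIVE_COLUMNS.items():
            if col == "VowIndex":
                raw = row.get(col)
                kwargs[attr] = None if raw is None or pd.isna(raw) else float(raw)
            elif col in _BOOL_COLUMNS:
                kwargs[attr] = _parse_bool(row[col])
            elif attr in ("lon", "lat"):
                try:
                    kwargs[attr] = float(row[col])
                except (TypeError, ValueError):
                    raise ValidationError(
                        f"{path} row {idx}: unparseable coordinate {row[col]!r}"
                    ) from None
            elif attr in ("id", "name", "tone_cat", "glot_c", "nv_pattern", "vlength"):
                kwargs[attr] = str(row[col])
            else:
                kwargs[attr] = int(row[col])
        try:
            rec = LanguageRecord(**kwargs)
        except ValidationError as exc:
            errors.append(f"row {idx} (id={row['id']}): {exc}")
            continue
        for col, attr in _DERIVED_COLUMNS.items():
            if col not in df.columns or pd.isna(row[col]):
                continue
            stored = _parse_bool(row[col]) if col in _BOOL_COLUMNS else float(row[col])
            current = getattr(rec, attr)
            if col in _BOOL_COLUMNS:
                mismatch = stored != current
            else:
                mismatch = abs(float(current) - stored) > 1e-6
            if mismatch:
                logger.warning(
                    "%s row %s: stored %s=%r disagrees with recomputed %r",
                    path, idx, col, stored, current,
                )
        records.append(rec)
    if errors:
        raise ValidationError(f"{path}: invalid rows:\n" + "\n".join(errors))
    return records
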