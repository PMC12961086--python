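"""Report-table I/O and lexicon-based valence classification.

Reports are carried as a pandas DataFrame with one row per report
(columns: id, reporter_id, date, x, y and optionally text, channel,
valence).  Dates are stored internally as Julian day J in 1..365; CSVs
use ISO-8601 dates.  Valence is coded from free text against a bilingual
lexicon: a report is negative if it contains an explicit concern term or
an implicit concern pattern, positive if it contains a positive term,
neutral if it has informative text without emotional content, and
unclassified if the text is empty.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

NEGATIVE = "negative"
POSITIVE = "positive"
NEUTRAL = "neutral"
UNCLASSIFIED = "unclassified"
NON_NEGATIVE = "non-negative"

REQUIRED_COLUMNS = ("id", "date", "x", "y")

# Julian days are mapped to dates in a fixed non-leap year for CSV round-trips.
_CSV_YEAR = 2023


@dataclass(frozen=True)
class ValenceLexicon:
    """Word lists used to code report valence from free text."""

    negative_terms: tuple[str, ...]
    positive_terms: tuple[str, ...]
    implicit_negative_patterns: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.negative_terms or not self.positive_terms:
            raise ValueError("lexicon term lists must be non-empty")
        if set(self.negative_terms) & set(self.positive_terms):
            raise ValueError("negative and positive term lists must be disjoint")


def load_lexicon(path: str | Path | None = None) -> ValenceLexicon:
    """Load a lexicon from YAML; the packaged bilingual default if no path."""
    if path is None:
        text = resources.files("wolfreports.data").joinpath("lexicon.yml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return ValenceLexicon(
        negative_terms=tuple(_fold(t) for t in raw["negative_terms"]),
        positive_terms=tuple(_fold(t) for t in raw["positive_terms"]),
        implicit_negative_patterns=tuple(_fold(t) for t in raw.get("implicit_negative_patterns", ())),
    )


def _fold(text: str) -> str:
    """Lowercase and strip accents so matching is case/accent-insensitive."""
    text = unicodedata.normalize("NFKD", str(text).lower())
    return "".join(ch for ch in text if not unicodedata.combining(ch))


def classify_valence(text: str | None, lexicon: ValenceLexicon) -> str:
    """Code one report's valence from its free-text message.

    Negative takes precedence over positive (a report mixing admiration
    and concern is coded by the concern).  Explicit terms match on word
    boundaries; implicit patterns match as substrings.
    """
    if text is None or not str(text).strip():
        return UNCLASSIFIED
    folded = _fold(text)
    for pat in lexicon.implicit_negative_patterns:
        if pat in folded:
            return NEGATIVE
    words = set(re.findall(r"[^\W\d_]+", folded))
    if words & set(lexicon.negative_terms):
        return NEGATIVE
    if words & set(lexicon.positive_terms):
        return POSITIVE
    return NEUTRAL


def merge_nonnegative(labels) -> np.ndarray:
    """Collapse positive and neutral into a single non-negative class."""
    labels = np.asarray(labels, dtype=object)
    if np.any(labels == UNCLASSIFIED):
        raise ValueError("cannot merge unclassified labels")
    bad = set(labels) - {NEGATIVE, POSITIVE, NEUTRAL}
    if bad:
        raise ValueError(f"unknown valence labels: {sorted(bad)}")
    return np.where(labels == NEGATIVE, NEGATIVE, NON_NEGATIVE)


def interrater_agreement(labels_a, labels_b) -> tuple[float, float]:
    """Proportion agreement and Cohen's kappa between two coders.

    Kappa is (p_o - p_e) / (1 - p_e) with p_e the chance agreement from
    the coders' marginal label frequencies; it is NaN when chance
    agreement is 1 (both coders constant on the same single label).
    """
    a = np.asarray(labels_a, dtype=object)
    b = np.asarray(labels_b, dtype=object)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    if len(a) == 0:
        raise ValueError("label vectors must be non-empty")
    po = float(np.mean(a == b))
    cats = sorted(set(a) | set(b))
    pa = np.array([np.mean(a == c) for c in cats])
    pb = np.array([np.mean(b == c) for c in cats])
    pe = float(pa @ pb)
    kappa = float("nan") if pe >= 1.0 - 1e-12 else (po - pe) / (1.0 - pe)
    return po, kappa


def valence_summary(n_negative: int, n_positive: int, n_neutral: int) -> dict[str, float]:
    """Shares of valenced/neutral reports and the split among valenced ones.

    Returns fractions in [0, 1]: ``valenced_share`` (+ ``neutral_share``
    = 1), and the negative/positive split among valenced reports (NaN
    when no report is valenced).
    """
    counts = (n_negative, n_positive, n_neutral)
    if any(c < 0 or int(c) != c for c in counts):
        raise ValueError("counts must be non-negative integers")
    total = sum(counts)
    if total == 0:
        raise ValueError("total count must be positive")
    valenced = n_negative + n_positive
    return {
        "valenced_share": valenced / total,
        "neutral_share": n_neutral / total,
        "negative_among_valenced": n_negative / valenced if valenced else float("nan"),
        "positive_among_valenced": n_positive / valenced if valenced else float("nan"),
    }


def read_reports(path: str | Path) -> pd.DataFrame:
    """Read a report CSV into the package's report DataFrame.

    Rows without coordinates are dropped (their count is logged and kept
    in ``df.attrs['n_dropped_missing_coords']``).  Dates may be ISO-8601
    strings or integer Julian days; unparseable dates raise, naming the
    report id.
    """
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"report table is missing required columns: {missing}")
    n0 = len(df)
    df = df.dropna(subset=["x", "y"]).reset_index(drop=True)
    n_dropped = n0 - len(df)
    if n_dropped:
        logger.info("dropped %d report(s) without ascertained coordinates", n_dropped)
    df["date"] = [_parse_julian(d, i) for d, i in zip(df["date"], df["id"])]
    if "reporter_id" not in df.columns:
        df["reporter_id"] = ""
    df["x"] = df["x"].astype(float)
    df["y"] = df["y"].astype(float)
    if not np.isfinite(df[["x", "y"]].to_numpy()).all():
        raise ValueError("report coordinates must be finite")
    df.attrs["n_dropped_missing_coords"] = n_dropped
    return df


def _parse_julian(value, report_id) -> int:
    try:
        if isinstance(value, (int, np.integer)) or (
            isinstance(value, float) and float(value).is_integer()
        ):
            j = int(value)
        else:
            ts = pd.Timestamp(str(value))
            j = min(int(ts.dayofyear), 365)  # Dec 31 of a leap year folds onto 365
        if not 1 <= j <= 365:
            raise ValueError
        return j
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparseable date {value!r} for report {report_id!r}") from exc


def write_reports(df: pd.DataFrame, path: str | Path) -> None:
    """Write reports to CSV with ISO-8601 dates (fixed non-leap year)."""
    out = df.copy()
    base = pd.Timestamp(f"{_CSV_YEAR}-01-01")
    out["date"] = [
        (base + pd.Timedelta(days=int(j) - 1)).date().isoformat() for j in out["date"]
    ]
    cols = [c for c in ("id", "reporter_id", "date", "x", "y", "text", "channel", "valence") if c in out.columns]
    out[cols].to_csv(path, index=False)
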