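"""Reading and writing post corpora, labels and the theme-mapping config.

The on-disk formats are deliberately plain: JSON-lines for posts (one
submission object per line, mirroring public Reddit dump schemas), TSV for
post labels, YAML for the subreddit -> theme mapping.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml

logger = logging.getLogger(__name__)

CONTROL_LABEL = "control"


@dataclass
class Post:
    """One authored, timestamped submission.

    ``created`` is an integer UTC epoch-second timestamp (the dump
    convention), which keeps day arithmetic lossless.
    """

    post_id: str
    author: str
    created: int
    subreddit: str
    title: str = ""
    body: str = ""

    def text(self) -> str:
        """Title concatenated with body, the unit of all text analysis."""
        return f"{self.title} {self.body}" if self.title else self.body


@dataclass(frozen=True)
class ThemeMap:
    """Ordered mapping of subreddits to mental-health condition themes.

    ``themes`` is the fixed, persisted theme order; it defines the class
    indices of every multiclass artifact. ``entries`` maps each subreddit
    (case-sensitive, Reddit names being canonical) to exactly one theme.
    """

    themes: tuple[str, ...]
    entries: dict[str, str] = field(hash=False)

    def __post_init__(self) -> None:
        seen = set(self.themes)
        if len(seen) != len(self.themes):
            raise ValueError("duplicate theme names")
        for sub, theme in self.entries.items():
            if theme not in seen:
                raise ValueError(f"subreddit {sub!r} maps to unknown theme {theme!r}")

    def theme_of(self, subreddit: str) -> str | None:
        return self.entries.get(subreddit)

    def subreddits_of(self, theme: str) -> list[str]:
        return [s for s, t in self.entries.items() if t == theme]

    def class_index(self, theme: str) -> int:
        return self.themes.index(theme)


def read_posts_jsonl(path: str | Path) -> list[Post]:
    """Read a JSON-lines corpus.

    Missing ``title``/``body`` become empty strings. Records missing
    ``author`` or ``created`` are skipped (the control construction needs
    both); the skip count is logged. A malformed line raises ``ValueError``
    naming the 1-based line number.
    """
    posts: list[Post] = []
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"malformed JSON on line {lineno} of {path}: {exc}") from exc
            if rec.get("author") is None or rec.get("created") is None:
                skipped += 1
                continue
            posts.append(
                Post(
                    post_id=str(rec.get("post_id", rec.get("id", f"line{lineno}"))),
                    author=str(rec["author"]),
                    created=int(rec["created"]),
                    subreddit=str(rec.get("subreddit", "")),
                    title=str(rec.get("title") or ""),
                    body=str(rec.get("body") or ""),
                )
            )
    if skipped:
        logger.warning("skipped %d records missing author/created in %s", skipped, path)
    return posts


def write_posts_jsonl(posts: Iterable[Post], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in posts:
            fh.write(
                json.dumps(
                    {
                        "post_id": p.post_id,
                        "author": p.author,
                        "created": p.created,
                        "subreddit": p.subreddit,
                        "title": p.title,
                        "body": p.body,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_labels_tsv(path: str | Path) -> dict[str, str]:
    """Read a (post_id, label) TSV into a dict."""
    labels: dict[str, str] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            labels[row[0]] = row[1]
    return labels


def write_labels_tsv(labels: dict[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for post_id, label in labels.items():
            w.writerow([post_id, label])


def dedupe_posts(posts: list[Post]) -> list[Post]:
    """Drop posts with an already-seen post_id, keeping the first."""
    seen: set[str] = set()
    out = []
    for p in posts:
        if p.post_id not in seen:
            seen.add(p.post_id)
            out.append(p)
    return out


def _default_theme_map_text() -> str:
    return resources.files("redthemes.data").joinpath("theme_map.yaml").read_text("utf-8")


def load_theme_map(path: str | Path | None = None) -> ThemeMap:
    """Load a theme map from YAML; with no path, the packaged default.

    The default reproduces the 11-theme grouping used throughout: e.g. the
    ``bipolar`` theme pools the BipolarSOs, BipolarReddit and bipolar
    subreddits, ``Opiates`` pools OpiatesRecovery and opiates, ``selfharm``
    pools selfharm and StopSelfHarm. A subreddit mapped to two themes is a
    configuration error.
    """
    if path is None:
        raw = yaml.safe_load(_default_theme_map_text())
    else:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    themes: list[str] = []
    entries: dict[str, str] = {}
    for block in raw["themes"]:
        name = str(block["name"])
        themes.append(name)
        for sub in block.get("subreddits", []):
            sub = str(sub)
            if sub in entries:
                raise ValueError(f"subreddit {sub!r} mapped to both {entries[sub]!r} and {name!r}")
            entries[sub] = name
    return ThemeMap(themes=tuple(themes), entries=entries)


def load_stopwords() -> frozenset[str]:
    """Frozen standard English stopword list shipped with the package."""
    text = resources.files("redthemes.data").joinpath("stopwords_en.txt").read_text("utf-8")
    return frozenset(w for w in text.split() if w)


def load_default_keywords() -> list[str]:
    """Small illustrative mental-health keyword list for subreddit discovery."""
    text = resources.files("redthemes.data").joinpath("keywords_default.txt").read_text("utf-8")
    return [w.strip() for w in text.splitlines() if w.strip() and not w.startswith("#")]
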