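"""Semi-automated trait curation from encyclopedia-style XML dumps.

Trait information for thousands of species often lives only in free text
(encyclopedia articles and similar).  This tool scans a MediaWiki-export
style XML dump for a regular expression associated with a trait (e.g.
``[Pp]arasit`` for parasitism), collects a context snippet around every
match together with candidate taxon names found in the snippet, and emits
a self-contained interactive HTML page: each candidate gets a checkbox,
selections and free-text entries accumulate into a single comma-separated
list that the reviewer compiles with one click and feeds back through
:func:`parse_selection_list`.  The selection step is deliberately manual —
the point of the pipeline is to make human curation fast, not to replace
it.
"""

from __future__ import annotations

import html
import re
from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

__all__ = [
    "ArticleMatch",
    "scan_articles",
    "render_review_html",
    "parse_selection_list",
]

DEFAULT_WINDOW = 300

_WIKILINK = re.compile(r"\[\[([^\]|]+)(?:\|[^\]]*)?\]\]")
_CAP_SPAN = re.compile(r"\b[A-Z][a-z]+(?: [a-z][a-z-]+)+\b")


@dataclass
class ArticleMatch:
    """One regex hit: the page it came from, its context, and candidates."""

    page_title: str
    snippet: str
    candidate_terms: list[str] = field(default_factory=list)


def _candidates(snippet: str) -> list[str]:
    """Candidate taxon names inside a snippet.

    Wiki-style link targets (``[[...]]``) are preferred; if the snippet
    has none, capitalized multi-word spans are used as a fallback.
    De-duplicated preserving order.
    """
    terms = [m.group(1).strip() for m in _WIKILINK.finditer(snippet)]
    if not terms:
        terms = [m.group(0) for m in _CAP_SPAN.finditer(snippet)]
    seen: set[str] = set()
    out = []
    for t in terms:
        if t and t not in seen:
            seen.add(t)
            out.append(t)
    return out


def scan_articles(
    xml_path, pattern: str, window: int = DEFAULT_WINDOW
) -> list[ArticleMatch]:
    """Scan an XML article dump for a regex; one match record per hit.

    The dump must contain ``page`` elements with a ``title`` and a text
    body (MediaWiki export layout; namespaces are ignored).  Snippets are
    ±``window`` characters clipped to the text boundaries; matches are
    returned in document order.
    """
    try:
        rx = re.compile(pattern)
    except re.error as exc:
        raise ValueError(f"invalid regular expression {pattern!r}: {exc}") from exc
    pages_done = 0
    matches: list[ArticleMatch] = []
    try:
        context = etree.iterparse(str(xml_path), events=("end",), recover=False)
        for _, elem in context:
            if etree.QName(elem).localname != "page":
                continue
            title = ""
            body = ""
            for node in elem.iter():
                name = etree.QName(node).localname
                if name == "title" and node.text:
                    title = node.text
                elif name == "text" and node.text:
                    body = node.text
            for m in rx.finditer(body):
                lo = max(0, m.start() - window)
                hi = min(len(body), m.end() + window)
                snippet = body[lo:hi]
                matches.append(
                    ArticleMatch(
                        page_title=title,
                        snippet=snippet,
                        candidate_terms=_candidates(snippet),
                    )
                )
            pages_done += 1
            elem.clear(keep_tail=True)
    except etree.XMLSyntaxError as exc:
        raise ValueError(
            f"malformed XML after {pages_done} page(s): {exc}"
        ) from exc
    return matches


_PAGE_TEMPLATE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>Trait review</title>
<style>
body {{ font-family: sans-serif; display: flex; gap: 2em; margin: 1em; }}
#matches {{ flex: 3; }} #panel {{ flex: 1; position: sticky; top: 1em;
  align-self: flex-start; }}
.match {{ border: 1px solid #ccc; border-radius: 6px; padding: 0.8em;
  margin-bottom: 1em; }}
.match h3 {{ margin: 0 0 0.4em 0; font-size: 1em; }}
.snippet {{ color: #333; font-size: 0.9em; white-space: pre-wrap; }}
textarea {{ width: 100%; height: 12em; }}
</style>
</head>
<body>
<div id="matches">
<h2>{count} match(es)</h2>
{blocks}
</div>
<div id="panel">
<h2>Selected terms</h2>
<textarea id="selected"></textarea>
<p><input type="text" id="manual" placeholder="add a term manually">
<button onclick="addManual()">Add</button></p>
<p><button onclick="compile()">Compile comma-separated list</button></p>
<textarea id="compiled" placeholder="compiled list appears here"></textarea>
</div>
<script>
function refresh() {{
  var boxes = document.querySelectorAll('input.term:checked');
  var terms = [];
  boxes.forEach(function(b) {{ terms.push(b.value); }});
  var manual = document.getElementById('selected').dataset.manual || '';
  if (manual) terms = terms.concat(manual.split('\\u0000'));
  document.getElementById('selected').value = terms.join('\\n');
}}
function addManual() {{
  var box = document.getElementById('manual');
  var sel = document.getElementById('selected');
  if (box.value.trim()) {{
    sel.dataset.manual = (sel.dataset.manual ? sel.dataset.manual + '\\u0000' : '')
      + box.value.trim();
    box.value = '';
    refresh();
  }}
}}
function compile() {{
  var lines = document.getElementById('selected').value.split('\\n');
  var seen = {{}};
  var out = [];
  lines.forEach(function(t) {{
    t = t.trim();
    if (t && !seen[t]) {{ seen[t] = true; out.push(t); }}
  }});
  document.getElementById('compiled').value = out.join(', ');
}}
document.addEventListener('change', function(e) {{
  if (e.target.classList.contains('term')) refresh();
}});
</script>
</body>
</html>
"""

_BLOCK_TEMPLATE = """<div class="match">
<h3>{title}</h3>
<div class="snippet">{snippet}</div>
<div class="terms">{checkboxes}</div>
</div>"""


def render_review_html(matches: list[ArticleMatch], out_path) -> Path:
    """Write the self-contained review page; returns the path written.

    Zero matches still produce a valid page stating so.  The page needs no
    network access: all style and behaviour is inline.
    """
    blocks = []
    for i, m in enumerate(matches):
        boxes = "".join(
            f'<label><input type="checkbox" class="term" '
            f'value="{html.escape(t, quote=True)}"> {html.escape(t)}</label><br>'
            for t in m.candidate_terms
        )
        blocks.append(
            _BLOCK_TEMPLATE.format(
                title=html.escape(m.page_title or f"match {i + 1}"),
                snippet=html.escape(m.snippet),
                checkboxes=boxes or "<em>no candidate terms</em>",
            )
        )
    page = _PAGE_TEMPLATE.format(count=len(matches), blocks="\n".join(blocks))
    out = Path(out_path)
    out.write_text(page, encoding="utf-8")
    return out


def parse_selection_list(text: str) -> list[str]:
    """Split a compiled comma-separated list into clean unique names.

    Whitespace is trimmed, empty entries dropped, duplicates removed
    preserving first-occurrence order.
    """
    seen: set[str] = set()
    out: list[str] = []
    for part in text.split(","):
        name = part.strip()
        if name and name not in seen:
            seen.add(name)
            out.append(name)
    return out
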