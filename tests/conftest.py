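import datetime

import pytest

from robmine import Document, default_pattern_sets


@pytest.fixture(scope="session")
def patterns():
    return default_pattern_sets()


@pytest.fixture
def make_corpus_dir(tmp_path):
    """Write a corpus directory + metadata CSV from (doc_id, text, journal, date) rows."""

    def _make(rows, metadata_rows=None, name="corpus"):
        d = tmp_path / name
        d.mkdir()
        for doc_id, text, *_ in rows:
            (d / f"{doc_id}.txt").write_text(text, encoding="utf-8")
        meta = d / "metadata.csv"
        lines = ["doc_id,journal,record_date"]
        for row in (metadata_rows if metadata_rows is not None else rows):
            doc_id = row[0]
            journal = row[2] if len(row) > 2 else "J"
            date = row[3] if len(row) > 3 else "2016-01-01"
            lines.append(f"{doc_id},{journal},{date}")
        meta.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return d, meta

    return _make


def doc(text, doc_id="d1", journal="J", date="2016-01-01"):
    return Document(doc_id=doc_id, text=text, journal=journal,
                    record_date=datetime.date.fromisoformat(date))
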