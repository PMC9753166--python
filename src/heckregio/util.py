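"""Small shared helpers."""

from __future__ import annotations

from contextlib import contextmanager

from rdkit import rdBase


@contextmanager
def quiet_rdkit():
    """Temporarily silence RDKit log output (atom-typing chatter for Pd,
    intentional unmapped-atom notes in the leaving-group rewrites)."""
    with rdBase.BlockLogs():
        yield
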