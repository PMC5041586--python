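import pytest

from qkat import (
    MarkerAssay,
    MultiplexReaction,
    Panel,
    builtin_panel,
    fixture_library,
)


@pytest.fixture(scope="session")
def kir_panel() -> Panel:
    return builtin_panel()


@pytest.fixture(scope="session")
def library():
    return fixture_library()


def make_mini_panel(replicates: int = 4) -> Panel:
    """Smallest valid panel: one duplex reaction (one target + reference)."""
    return Panel(
        name="mini",
        markers=[
            MarkerAssay("M1", gene="G1", channel="FAM"),
            MarkerAssay("REF", gene="REFG", channel="Cy5", is_reference=True),
        ],
        reactions=[MultiplexReaction("R1", ("M1",), "REF")],
        replicates=replicates,
    )


@pytest.fixture
def mini_panel() -> Panel:
    return make_mini_panel()
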