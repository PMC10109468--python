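import pytest

from palynoscope.geometry import TileGrid


@pytest.fixture(scope="session")
def survey_grid() -> TileGrid:
    """Acquisition geometry of the reference survey: 60x60 tiles of
    6144x4090 px, 120-um FOV, 12.5% overlap, 8 s dwell."""
    return TileGrid(
        n_cols=60,
        n_rows=60,
        tile_px_x=6144,
        tile_px_y=4090,
        fov_width_um=120.0,
        overlap_frac=0.125,
        dwell_s_per_image=8.0,
    )


@pytest.fixture(scope="session")
def small_grid() -> TileGrid:
    """A 10x10 montage of square 100-um tiles, handy for exhaustive checks."""
    return TileGrid(
        n_cols=10,
        n_rows=10,
        tile_px_x=1000,
        tile_px_y=1000,
        fov_width_um=100.0,
        overlap_frac=0.125,
        dwell_s_per_image=8.0,
    )


def make_response(
    image_id="img",
    volunteer_id="v0",
    order_index=1,
    focus="in_focus",
    occurrence="fossil",
    count=1,
    position="middle",
    name="Nothofagidites",
):
    """Response factory; no_fossil zeroes the dependent answers."""
    from palynoscope.consensus import Response

    if occurrence == "no_fossil":
        count, position, name = 0, "none", "none"
    return Response(image_id, volunteer_id, order_index, focus, occurrence, count, position, name)
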