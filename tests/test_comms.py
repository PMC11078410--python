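"""Wire codec (340-byte SBD budget) and operator-hub exchange logic."""

import struct

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bloommap import (
    CellRecord,
    MessageHeader,
    OperatorHub,
    QuantizationScheme,
    decode_message,
    encode_message,
    max_records,
)
from bloommap.comms import (
    HEADER_SIZE,
    MSG_HUB_REPLY,
    MSG_VEHICLE_REPORT,
    PAYLOAD_BUDGET,
    SBD_LIMIT,
    hexdump,
)


class TestBudgetArithmetic:
    @pytest.mark.parametrize("n_c,expected", [(1, 80), (4, 45), (317, 1)])
    def test_record_capacity(self, n_c, expected):
        assert max_records(n_c) == expected

    def test_budget_constants(self):
        assert SBD_LIMIT == 340
        assert PAYLOAD_BUDGET == 320
        assert HEADER_SIZE == 10


def _records(n, n_c=1, start_time_code=200):
    """n records, newest first (descending time codes)."""
    return [
        CellRecord(i, tuple((i + j) % 256 for j in range(n_c)), max(start_time_code - i, 0))
        for i in range(n)
    ]


class TestEncodeDecode:
    def test_empty_queue_gives_header_only(self):
        msg = encode_message(MessageHeader(1, 3, 78.95, 11.94), [], n_c=1)
        assert len(msg) == 10

    def test_header_byte_offsets(self):
        msg = encode_message(MessageHeader(1, 7, 78.95, 11.94), _records(2), n_c=1)
        assert msg[0] == 1  # message ID at byte 0
        assert msg[1] == 7  # vehicle ID at byte 1
        assert struct.unpack(">f", msg[2:6])[0] == pytest.approx(78.95, abs=1e-4)
        assert struct.unpack(">f", msg[6:10])[0] == pytest.approx(11.94, abs=1e-4)

    def test_record_byte_offsets_nc1(self):
        recs = [CellRecord(2249, (0x7F,), 42), CellRecord(3, (0x01,), 41)]
        msg = encode_message(MessageHeader(1, 0, 0.0, 0.0), recs, n_c=1)
        # record k fields at 10+k*n_d (data), 11+k*n_d (cell no), 13+k*n_d (time)
        for k, rec in enumerate(recs):
            base = 10 + k * 4
            assert msg[base] == rec.data_codes[0]
            assert struct.unpack(">H", msg[base + 1 : base + 3])[0] == rec.cell_no
            assert msg[base + 3] == rec.time_code

    def test_truncates_to_newest_80_of_100(self):
        msg = encode_message(MessageHeader(1, 0, 0.0, 0.0), _records(100), n_c=1)
        assert len(msg) == 330  # 10 + 80*4
        _, recs = decode_message(msg, n_c=1)
        assert len(recs) == 80
        assert [r.cell_no for r in recs] == list(range(80))  # the newest kept

    @pytest.mark.parametrize("n_queue,n_c", [(0, 1), (5, 1), (200, 1), (50, 4), (3, 300)])
    def test_never_exceeds_sbd_limit(self, n_queue, n_c):
        msg = encode_message(MessageHeader(1, 0, 0.0, 0.0), _records(n_queue, n_c), n_c)
        assert len(msg) <= 340
        assert (len(msg) - 10) % (3 + n_c) == 0

    def test_decode_rejects_malformed_length(self):
        msg = encode_message(MessageHeader(1, 0, 0.0, 0.0), _records(2), n_c=1)
        with pytest.raises(ValueError):
            decode_message(msg[:-1], n_c=1)
        with pytest.raises(ValueError):
            decode_message(msg[:5], n_c=1)

    def test_decode_rejects_unknown_message_id(self):
        msg = bytearray(encode_message(MessageHeader(1, 0, 0.0, 0.0), [], n_c=1))
        msg[0] = 99
        with pytest.raises(ValueError):
            decode_message(bytes(msg), n_c=1)

    def test_cell_number_over_capacity_rejected(self):
        with pytest.raises(ValueError):
            CellRecord(65_536, (0,), 0)

    @settings(max_examples=200, deadline=None)
    @given(
        vehicle=st.integers(0, 255),
        lat=st.floats(-90, 90, width=32),
        lon=st.floats(-180, 180, width=32),
        n_c=st.integers(1, 6),
        data=st.data(),
    )
    def test_roundtrip_fuzz(self, vehicle, lat, lon, n_c, data):
        """encode -> decode is the identity on codes for arbitrary messages."""
        n_rec = data.draw(st.integers(0, max_records(n_c)))
        recs = [
            CellRecord(
                data.draw(st.integers(0, 65_535)),
                tuple(data.draw(st.integers(0, 255)) for _ in range(n_c)),
                data.draw(st.integers(0, 255)),
            )
            for _ in range(n_rec)
        ]
        msg = encode_message(MessageHeader(1, vehicle, lat, lon), recs, n_c)
        assert len(msg) <= 340
        assert len(msg) == 10 + n_rec * (3 + n_c)
        header, out = decode_message(msg, n_c)
        assert header.vehicle_id == vehicle
        assert out == recs
        # decoded floats are the float32 representation of the inputs
        assert header.lat == pytest.approx(lat, abs=1e-4) or np.isclose(
            header.lat, np.float32(lat)
        )


class TestQuantization:
    def test_endpoint_codes(self):
        q = QuantizationScheme(channel_ranges=((0.01, 100.0),))
        assert q.encode_value(0.01) == 0
        assert q.encode_value(100.0) == 255
        assert q.encode_value(0.0001) == 0  # clipped below
        assert q.encode_value(1e6) == 255  # clipped above

    def test_error_bound_on_log_scale(self, rng):
        q = QuantizationScheme(channel_ranges=((0.01, 100.0),))
        lo, hi = 0.01, 100.0
        half_step = (np.log(hi) - np.log(lo)) / (2 * 255)
        for v in np.exp(rng.uniform(np.log(lo), np.log(hi), 500)):
            back = q.decode_value(q.encode_value(v))
            assert abs(np.log(back) - np.log(v)) <= half_step + 1e-12

    def test_code_roundtrip_idempotent(self):
        q = QuantizationScheme()
        for code in range(256):
            assert q.encode_value(q.decode_value(code)) == code

    def test_time_code_saturates(self):
        q = QuantizationScheme(time_step=60.0)
        assert q.encode_time(0.0) == 0
        assert q.encode_time(61.0) == 1
        assert q.encode_time(1e9) == 255


class TestOperatorHub:
    def _report(self, vid, cells, t0=100):
        recs = [CellRecord(c, (10 + c,), t0 + i) for i, c in enumerate(cells)]
        recs = sorted(recs, key=lambda r: -r.time_code)
        return encode_message(MessageHeader(MSG_VEHICLE_REPORT, vid, 78.9, 11.9), recs, 1)

    def test_two_vehicle_relay(self):
        hub = OperatorHub(n_c=1)
        hub.exchange(self._report(0, [1, 2]), now=10.0)
        positions, reply = hub.exchange(self._report(1, [9]), now=20.0)
        assert 0 in positions  # A's surface position forwarded to B
        header, recs = decode_message(reply, 1)
        assert header.message_id == MSG_HUB_REPLY
        assert sorted(r.cell_no for r in recs) == [1, 2]  # A's cells forwarded

    def test_single_vehicle_reply_is_empty(self):
        hub = OperatorHub(n_c=1)
        positions, reply = hub.exchange(self._report(0, [1, 2]), now=0.0)
        assert positions == {}
        assert len(reply) == 10

    def test_newer_report_wins_per_cell(self):
        hub = OperatorHub(n_c=1)
        old = encode_message(
            MessageHeader(1, 0, 0.0, 0.0), [CellRecord(5, (1,), 10)], 1
        )
        new = encode_message(
            MessageHeader(1, 0, 0.0, 0.0), [CellRecord(5, (2,), 20)], 1
        )
        hub.exchange(old, now=0.0)
        hub.exchange(new, now=1.0)
        _, reply = hub.exchange(self._report(1, []), now=2.0)
        _, recs = decode_message(reply, 1)
        assert len(recs) == 1
        assert recs[0].data_codes == (2,)

    def test_no_endless_resend(self):
        hub = OperatorHub(n_c=1)
        hub.exchange(self._report(0, [1, 2, 3]), now=0.0)
        _, reply1 = hub.exchange(self._report(1, []), now=1.0)
        _, reply2 = hub.exchange(self._report(1, []), now=2.0)
        assert len(decode_message(reply1, 1)[1]) == 3
        assert len(decode_message(reply2, 1)[1]) == 0  # already delivered

    def test_reply_respects_sbd_budget(self):
        hub = OperatorHub(n_c=1)
        # vehicle 0 reports 80 cells twice (160 records at the hub)
        hub.exchange(self._report(0, list(range(80)), t0=10), now=0.0)
        hub.exchange(self._report(0, list(range(80, 160)), t0=95), now=1.0)
        _, reply = hub.exchange(self._report(1, []), now=2.0)
        assert len(reply) <= 340
        assert len(decode_message(reply, 1)[1]) == 80

    def test_eventual_consistency_of_shared_grid(self):
        """With no new sampling, repeated exchange rounds make every
        vehicle's view of the reported cells identical."""
        hub = OperatorHub(n_c=1)
        reports = {0: [1, 2], 1: [30, 31, 32], 2: [60]}
        views = {vid: {} for vid in reports}  # cell -> data code

        def do_round():
            for vid, cells in reports.items():
                msg = self._report(vid, cells if first_round else [])
                _, reply = hub.exchange(msg, now=0.0)
                for rec in decode_message(reply, 1)[1]:
                    views[vid][rec.cell_no] = rec.data_codes
                for c in cells:  # own cells always known locally
                    views[vid][c] = (10 + c,)

        first_round = True
        do_round()
        first_round = False
        do_round()
        all_cells = sorted(c for cells in reports.values() for c in cells)
        for vid in reports:
            assert sorted(views[vid]) == all_cells
        ref = views[0]
        assert all(views[v] == ref for v in reports)


def test_hexdump_shows_offsets():
    msg = encode_message(MessageHeader(1, 2, 0.0, 0.0), _records(1), 1)
    dump = hexdump(msg)
    assert dump.startswith("0000")
    assert "01 02" in dump
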