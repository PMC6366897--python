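"""Wire protocol for hub <-> client communication.

Parameter messages are fixed-length text frames: an integer identifier, a
space, the value text, a space, then a run of ``'q'`` padding characters
terminated by ``'/'``, for a total of exactly :data:`FRAME_LEN` characters.
For example identifier ``-106`` with value ``"one"`` renders as
``"-106 one qqq...q/"``.

Event codes (trial markers such as *stimulus on* or *fixation broken*) travel
over the same frame format on a reserved identifier band, so a single codec
serves both the parameter-update path and the event path.

Two transport flavors are provided over stdlib sockets — unordered/unreliable
datagrams (UDP) and ordered/reliable streams (TCP) — plus an in-memory
loopback channel used by the deterministic simulated sessions.  All channels
share one contract: :meth:`Channel.poll` never blocks; it returns immediately
with zero or more complete frames so a control loop never pauses waiting for
a remote peer.
"""

from __future__ import annotations

import re
import socket
from abc import ABC, abstractmethod
from collections import deque
from dataclasses import dataclass
from typing import Deque, Iterable, Iterator, Mapping

FRAME_LEN = 1024
"""Rendered frame length in characters (7-bit text: characters == bytes)."""

_TERMINATOR_RE = re.compile(r"q+/\Z")


class ProtocolError(ValueError):
    """Base class for frame codec errors."""


class FrameOverflowError(ProtocolError):
    """Identifier + value + minimal padding do not fit in FRAME_LEN."""


class InvalidValueError(ProtocolError):
    """Value text cannot survive a frame round trip (newline, odd spacing)."""


class MalformedFrameError(ProtocolError):
    """Received text is not a valid frame."""


class ChannelClosedError(RuntimeError):
    """Operation on a closed channel."""


def encode_param(identifier: int, value: str = "") -> str:
    """Render an identifier/value pair as a fixed-length frame.

    The frame is ``"<identifier> <value> "`` followed by ``'q'`` padding and a
    final ``'/'``; at least one padding ``'q'`` is always present so the
    terminator is a distinct whitespace-separated token (this is what makes
    values consisting only of ``'q'`` characters legal).

    Raises
    ------
    InvalidValueError
        If the value contains a newline, leading/trailing whitespace, or runs
        of internal whitespace (any of which would not round-trip).
    FrameOverflowError
        If the payload leaves no room for the minimal ``"q/"`` terminator.
    """
    identifier = int(identifier)
    if not isinstance(value, str):
        raise InvalidValueError(f"value must be str, got {type(value).__name__}")
    if value != "" and value != " ".join(value.split()):
        raise InvalidValueError(
            "value must be single-spaced printable text with no leading/"
            f"trailing whitespace: {value!r}"
        )
    body = f"{identifier} {value} " if value else f"{identifier} "
    pad = FRAME_LEN - len(body) - 1  # -1 for the trailing '/'
    if pad < 1:
        raise FrameOverflowError(
            f"payload of {len(body)} characters leaves no room for the "
            f"terminator in a {FRAME_LEN}-character frame"
        )
    return body + "q" * pad + "/"


def decode_param(frame: str) -> tuple[int, str]:
    """Inverse of :func:`encode_param`.

    Splits on whitespace; the first token is the integer identifier, the last
    token must be the ``q+/`` terminator, and the value is the intervening
    tokens rejoined with single spaces.
    """
    if not isinstance(frame, str) or len(frame) != FRAME_LEN:
        raise MalformedFrameError(
            f"frame must be exactly {FRAME_LEN} characters, "
            f"got {len(frame) if isinstance(frame, str) else type(frame).__name__}"
        )
    tokens = frame.split()
    if len(tokens) < 2:
        raise MalformedFrameError("frame must contain an identifier and a terminator")
    try:
        identifier = int(tokens[0])
    except ValueError as exc:
        raise MalformedFrameError(f"identifier token {tokens[0]!r} is not an integer") from exc
    if not _TERMINATOR_RE.fullmatch(tokens[-1]):
        raise MalformedFrameError(f"bad terminator token {tokens[-1]!r}")
    return identifier, " ".join(tokens[1:-1])


# ---------------------------------------------------------------------------
# Event codes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EventCode:
    """A registered trial event: integer code, human label, emitting group."""

    code: int
    label: str
    source: str  # {"control", "stimulus", "tracker"}


# Event codes live on a reserved identifier band (|code| >= 900) so they never
# collide with parameter identifiers such as -106.  Negative codes are
# stimulus-related commands; positive codes are behavior-related status events.
DEFAULT_EVENT_CODES: tuple[EventCode, ...] = (
    EventCode(-901, "fixation_target_on", "stimulus"),
    EventCode(-902, "fixation_target_off", "stimulus"),
    EventCode(-903, "stimulus_on", "stimulus"),
    EventCode(-904, "stimulus_off", "stimulus"),
    EventCode(-905, "choice_targets_on", "stimulus"),
    EventCode(-906, "choice_targets_off", "stimulus"),
    EventCode(-907, "shock_on", "control"),
    EventCode(-908, "shock_off", "control"),
    EventCode(901, "trial_start", "control"),
    EventCode(902, "fixation_acquired", "control"),
    EventCode(903, "fixation_broken", "control"),
    EventCode(904, "choice_made", "control"),
    EventCode(905, "reward_delivered", "control"),
    EventCode(906, "trial_abort", "control"),
    EventCode(907, "trial_end", "control"),
    EventCode(908, "gate_open", "control"),
    EventCode(909, "dark_entry", "tracker"),
    EventCode(910, "session_end", "control"),
    EventCode(999, "sync", "control"),
)


class EventRegistry:
    """Bidirectional code <-> label lookup; codes and labels are unique."""

    def __init__(self, codes: Iterable[EventCode] = DEFAULT_EVENT_CODES):
        self.by_code: dict[int, EventCode] = {}
        self.by_label: dict[str, EventCode] = {}
        for ev in codes:
            if ev.code in self.by_code:
                raise ValueError(f"duplicate event code {ev.code}")
            if ev.label in self.by_label:
                raise ValueError(f"duplicate event label {ev.label!r}")
            self.by_code[ev.code] = ev
            self.by_label[ev.label] = ev

    def __getitem__(self, label: str) -> EventCode:
        return self.by_label[label]

    def __contains__(self, label: str) -> bool:
        return label in self.by_label

    def __iter__(self) -> Iterator[EventCode]:
        return iter(self.by_code.values())

    def encode(self, label: str, timestamp_ms: float) -> str:
        """Render an event as a ParamFrame carrying its timestamp."""
        ev = self.by_label[label]
        return encode_param(ev.code, f"{timestamp_ms:.3f}")

    def decode(self, frame: str) -> tuple[EventCode, float] | None:
        """Decode a frame; returns (event, timestamp) or None if the
        identifier is outside the event band."""
        code, value = decode_param(frame)
        if code not in self.by_code:
            return None
        return self.by_code[code], float(value)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Mapping[str, object]]) -> "EventRegistry":
        """Build from a config mapping ``label -> {code, source}``."""
        return cls(
            EventCode(int(spec["code"]), label, str(spec.get("source", "control")))
            for label, spec in mapping.items()
        )

    def to_mapping(self) -> dict[str, dict[str, object]]:
        return {ev.label: {"code": ev.code, "source": ev.source} for ev in self}


# ---------------------------------------------------------------------------
# Channels
# ---------------------------------------------------------------------------

class Channel(ABC):
    """A frame transport endpoint with a strictly non-blocking poll."""

    closed: bool = False

    @abstractmethod
    def send(self, frame: str) -> None:
        """Enqueue one frame for the remote endpoint."""

    @abstractmethod
    def poll(self) -> list[str]:
        """Return all complete frames received so far; never blocks."""

    def close(self) -> None:
        self.closed = True

    def _check_open(self) -> None:
        if self.closed:
            raise ChannelClosedError("channel is closed")


class LoopbackChannel(Channel):
    """Deterministic in-memory endpoint used by simulated sessions.

    Two endpoints share a pair of deques; FIFO order is preserved (the
    ordered-reliable contract).  Use :func:`loopback_pair` to build a
    connected pair.
    """

    def __init__(self, rx: Deque[str], tx: Deque[str]):
        self._rx = rx
        self._tx = tx

    def send(self, frame: str) -> None:
        self._check_open()
        if len(frame) != FRAME_LEN:
            raise MalformedFrameError("only full frames may be sent")
        self._tx.append(frame)

    def poll(self) -> list[str]:
        self._check_open()
        out = list(self._rx)
        self._rx.clear()
        return out


def loopback_pair() -> tuple[LoopbackChannel, LoopbackChannel]:
    a_to_b: Deque[str] = deque()
    b_to_a: Deque[str] = deque()
    return LoopbackChannel(b_to_a, a_to_b), LoopbackChannel(a_to_b, b_to_a)


class UdpChannel(Channel):
    """Unordered-unreliable datagram endpoint (one frame per datagram)."""

    transport = "unordered-unreliable"

    def __init__(self, local: tuple[str, int] = ("127.0.0.1", 0),
                 remote: tuple[str, int] | None = None):
        self.sock = socket.socket(socket.AF_INET, socket.SOCK_DGRAM)
        self.sock.bind(local)
        self.sock.setblocking(False)
        self.local = self.sock.getsockname()
        self.remote = remote

    def connect_to(self, remote: tuple[str, int]) -> None:
        self.remote = remote

    def send(self, frame: str) -> None:
        self._check_open()
        if self.remote is None:
            raise ChannelClosedError("no remote endpoint configured")
        self.sock.sendto(frame.encode("ascii"), self.remote)

    def poll(self) -> list[str]:
        self._check_open()
        frames: list[str] = []
        while True:
            try:
                data, _addr = self.sock.recvfrom(FRAME_LEN * 4)
            except BlockingIOError:
                break
            frames.append(data.decode("ascii"))
        return frames

    def close(self) -> None:
        if not self.closed:
            self.sock.close()
        super().close()


class TcpChannel(Channel):
    """Ordered-reliable stream endpoint; frames are fixed-size slices."""

    transport = "ordered-reliable"

    def __init__(self, sock: socket.socket):
        sock.setblocking(False)
        sock.setsockopt(socket.IPPROTO_TCP, socket.TCP_NODELAY, 1)
        self.sock = sock
        self._buf = b""

    def send(self, frame: str) -> None:
        self._check_open()
        if len(frame) != FRAME_LEN:
            raise MalformedFrameError("only full frames may be sent")
        self.sock.setblocking(True)
        try:
            self.sock.sendall(frame.encode("ascii"))
        finally:
            self.sock.setblocking(False)

    def poll(self) -> list[str]:
        self._check_open()
        while True:
            try:
                chunk = self.sock.recv(65536)
            except BlockingIOError:
                break
            if not chunk:
                break
            self._buf += chunk
        frames: list[str] = []
        while len(self._buf) >= FRAME_LEN:
            frames.append(self._buf[:FRAME_LEN].decode("ascii"))
            self._buf = self._buf[FRAME_LEN:]
        return frames

    def close(self) -> None:
        if not self.closed:
            self.sock.close()
        super().close()


def tcp_pair(host: str = "127.0.0.1") -> tuple[TcpChannel, TcpChannel]:
    """Connected TCP channel pair on loopback (test/benchmark convenience)."""
    listener = socket.socket(socket.AF_INET, socket.SOCK_STREAM)
    listener.bind((host, 0))
    listener.listen(1)
    client = socket.socket(socket.AF_INET, socket.SOCK_STREAM)
    client.connect(listener.getsockname())
    server, _ = listener.accept()
    listener.close()
    return TcpChannel(client), TcpChannel(server)


def udp_pair(host: str = "127.0.0.1") -> tuple[UdpChannel, UdpChannel]:
    """Mutually-connected UDP channel pair on loopback."""
    a = UdpChannel((host, 0))
    b = UdpChannel((host, 0))
    a.connect_to(b.local)
    b.connect_to(a.local)
    return a, b
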