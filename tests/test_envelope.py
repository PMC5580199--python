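"""Hybrid envelope: round trips, tamper detection, key-length contracts.

RSA test keys are 1024-bit and seeded for speed; the default key size is
2048 bits and exercised once.
"""

from __future__ import annotations

import json
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asthmawatch._aes import AES, pkcs7_pad, pkcs7_unpad
from asthmawatch._rsa import DecryptionError, generate_keypair, oaep_decrypt, oaep_encrypt
from asthmawatch.envelope import (
    Envelope,
    EnvelopeError,
    IntegrityError,
    KeyRegistry,
    decrypt_at_rest,
    open_envelope,
    reencrypt_at_rest,
    seal,
)


@pytest.fixture(scope="module")
def keypair():
    return generate_keypair(bits=1024, rng=random.Random(12345))


@pytest.fixture(scope="module")
def other_keypair():
    return generate_keypair(bits=1024, rng=random.Random(54321))


class TestAESPrimitives:
    def test_standard_known_answer_vectors(self):
        # the published AES test vectors for 128- and 256-bit keys
        pt = bytes.fromhex("00112233445566778899aabbccddeeff")
        assert AES(bytes(range(16))).encrypt_block(pt).hex() == (
            "69c4e0d86a7b0430d8cdb78070b4c55a"
        )
        assert AES(bytes(range(32))).encrypt_block(pt).hex() == (
            "8ea2b7ca516745bfeafc49904b496089"
        )

    def test_block_decrypt_inverts_encrypt(self):
        key = bytes(range(100, 132))
        cipher = AES(key)
        block = bytes(range(16))
        assert cipher.decrypt_block(cipher.encrypt_block(block)) == block

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(data=st.binary(min_size=0, max_size=4096), key=st.binary(min_size=16, max_size=16))
    def test_ctr_is_an_involution(self, data, key):
        cipher = AES(key)
        iv = b"\xab" * 16
        assert cipher.ctr_xor(iv, cipher.ctr_xor(iv, data)) == data

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(data=st.binary(min_size=0, max_size=1024))
    def test_cbc_round_trip_with_padding(self, data):
        cipher = AES(bytes(32))
        iv = b"\x01" * 16
        ct = cipher.cbc_encrypt(iv, pkcs7_pad(data))
        assert pkcs7_unpad(cipher.cbc_decrypt(iv, ct)) == data

    def test_invalid_key_lengths_rejected(self):
        for n in (0, 8, 24, 33):
            with pytest.raises(ValueError):
                AES(bytes(n))

    def test_ctr_counter_wraps_modulo_128_bits(self):
        cipher = AES(bytes(16))
        iv = b"\xff" * 16
        data = bytes(48)
        assert cipher.ctr_xor(iv, cipher.ctr_xor(iv, data)) == data


class TestRSA:
    def test_oaep_round_trip(self, keypair):
        msg = b"\x00\x01 short key material \xff"
        assert oaep_decrypt(keypair, oaep_encrypt(keypair.public_key, msg)) == msg

    def test_wrong_key_fails_loudly(self, keypair, other_keypair):
        ct = oaep_encrypt(keypair.public_key, b"secret")
        with pytest.raises(DecryptionError):
            oaep_decrypt(other_keypair, ct)

    def test_message_too_long_rejected(self, keypair):
        with pytest.raises(ValueError):
            oaep_encrypt(keypair.public_key, bytes(200))

    def test_default_key_size_is_2048_bits(self):
        key = generate_keypair(rng=random.Random(99))
        assert key.n.bit_length() == 2048


class TestEnvelopeRoundTrip:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(payload=st.binary(min_size=1, max_size=8192))
    def test_open_seal_identity(self, payload, keypair):
        assert open_envelope(seal(payload, keypair.public_key), keypair) == payload

    def test_large_payload_round_trip(self, keypair):
        payload = random.Random(1).randbytes(1 << 20)  # 1 MiB
        assert open_envelope(seal(payload, keypair.public_key), keypair) == payload

    def test_one_byte_payload(self, keypair):
        assert open_envelope(seal(b"x", keypair.public_key), keypair) == b"x"

    def test_empty_payload_rejected(self, keypair):
        with pytest.raises(EnvelopeError):
            seal(b"", keypair.public_key)

    def test_fresh_keys_give_distinct_ciphertexts(self, keypair):
        a = seal(b"same payload", keypair.public_key)
        b = seal(b"same payload", keypair.public_key)
        assert a.ciphertext != b.ciphertext
        assert a.wrapped_key != b.wrapped_key

    def test_plaintext_not_visible_in_envelope_fields(self, keypair):
        marker = b"MARKER-THAT-MUST-NOT-LEAK-0123456789"
        envelope = seal(marker * 4, keypair.public_key)
        for blob in (envelope.ciphertext, envelope.iv, envelope.wrapped_key):
            assert marker not in blob

    def test_json_serialization_round_trip(self, keypair):
        envelope = seal(b"payload bytes", keypair.public_key, key_id="cloud-1")
        back = Envelope.from_json(envelope.to_json())
        assert back == envelope
        assert set(json.loads(envelope.to_json())) == {
            "key_id", "iv", "wrapped_key", "ciphertext", "digest",
        }
        assert open_envelope(back, keypair) == b"payload bytes"


class TestTampering:
    def test_flipped_ciphertext_bit_fails_integrity(self, keypair):
        envelope = seal(b"sensitive record", keypair.public_key)
        ct = bytearray(envelope.ciphertext)
        ct[0] ^= 0x01
        tampered = Envelope(
            envelope.key_id, envelope.iv, envelope.wrapped_key, bytes(ct),
            envelope.payload_digest,
        )
        with pytest.raises(IntegrityError):
            open_envelope(tampered, keypair)

    def test_flipped_tag_bit_fails_integrity(self, keypair):
        envelope = seal(b"sensitive record", keypair.public_key)
        ct = bytearray(envelope.ciphertext)
        ct[-1] ^= 0x80
        tampered = Envelope(
            envelope.key_id, envelope.iv, envelope.wrapped_key, bytes(ct),
            envelope.payload_digest,
        )
        with pytest.raises(IntegrityError):
            open_envelope(tampered, keypair)

    def test_mismatched_key_pair_fails_decryption(self, keypair, other_keypair):
        envelope = seal(b"sensitive record", keypair.public_key)
        with pytest.raises(DecryptionError):
            open_envelope(envelope, other_keypair)


class TestAtRest:
    STORAGE_KEY = bytes(range(32))

    def test_round_trip_identity(self):
        blob = reencrypt_at_rest(b"rest payload", self.STORAGE_KEY)
        assert decrypt_at_rest(blob, self.STORAGE_KEY) == b"rest payload"

    def test_128_bit_key_rejected_for_storage(self):
        with pytest.raises(EnvelopeError):
            reencrypt_at_rest(b"data", bytes(16))
        with pytest.raises(EnvelopeError):
            decrypt_at_rest(bytes(48), bytes(16))

    def test_fresh_iv_gives_distinct_blobs(self):
        a = reencrypt_at_rest(b"data", self.STORAGE_KEY)
        b = reencrypt_at_rest(b"data", self.STORAGE_KEY)
        assert a != b

    def test_tampered_blob_fails_loudly(self):
        blob = bytearray(reencrypt_at_rest(b"stored record", self.STORAGE_KEY))
        blob[20] ^= 0x01
        with pytest.raises(IntegrityError):
            decrypt_at_rest(bytes(blob), self.STORAGE_KEY)

    def test_wrong_storage_key_fails_loudly(self):
        blob = reencrypt_at_rest(b"stored record", self.STORAGE_KEY)
        with pytest.raises(IntegrityError):
            decrypt_at_rest(blob, bytes(32))


class TestKeyRegistry:
    def test_generate_and_fetch(self):
        reg = KeyRegistry()
        key_id = reg.generate(bits=1024, rng=random.Random(3))
        assert reg.public(key_id).n == reg.private(key_id).n

    def test_duplicate_key_id_rejected(self):
        reg = KeyRegistry()
        reg.generate(bits=1024, key_id="k", rng=random.Random(4))
        with pytest.raises(EnvelopeError):
            reg.generate(bits=1024, key_id="k", rng=random.Random(5))

    def test_unknown_key_id_rejected(self):
        with pytest.raises(EnvelopeError):
            KeyRegistry().public("nope")
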