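algorithm	mirna	gene
targetscan	miR-27a/miR-27b	GATA2
targetscan	miR-27a/miR-27b	RXRA
targetscan	miR-27a/miR-27b	PPARG
targetscan	miR-27a/miR-27b	NFE2L2
targetscan	miR-27a/miR-27b	MYCN
miranda	miR-27a/miR-27b	GATA2
miranda	miR-27a/miR-27b	RXRA
miranda	miR-27a/miR-27b	PPARG
miranda	miR-27a/miR-27b	NFE2L2
miranda	miR-27a/miR-27b	MYCN
targetscan	miR-144	GATA2
targetscan	miR-144	NFE2L2
targetscan	miR-144	MYCN
miranda	miR-144	GATA2
miranda	miR-144	NFE2L2
miranda	miR-144	MYCN
miranda	miR-144	EGR1
targetscan	miR-128	GATA2
targetscan	miR-128	RXRA
targetscan	miR-128	NKX2-5
miranda	miR-128	GATA2
miranda	miR-128	RXRA
miranda	miR-128	NKX2-5
targetscan	miR-101a/miR-101b	PPARG
miranda	miR-101a/miR-101b	PPARG
miranda	miR-101a/miR-101b	RXRA
miranda	miR-101a/miR-101b	NFE2L2
miranda	miR-101a/miR-101b	SREBF1
targetscan	miR-200a/miR-200b/miR-200c	PPARG
targetscan	miR-200a/miR-200b/miR-200c	RXRA
miranda	miR-200a/miR-200b/miR-200c	PPARG
miranda	miR-200a/miR-200b/miR-200c	RXRA
targetscan	miR-124	PPARG
targetscan	miR-124	RXRA
targetscan	miR-124	NFE2L2
miranda	miR-124	PPARG
targetscan	miR-103	PPARG
miranda	miR-103	PPARG
miranda	miR-103	RXRA
targetscan	miR-106b	PPARG
miranda	miR-106b	PPARG
miranda	miR-106b	RXRA
targetscan	miR-132	PPARG
miranda	miR-132	PPARG
miranda	miR-132	RXRA
targetscan	miR-153	PPARG
miranda	miR-153	PPARG
miranda	miR-153	RXRA
targetscan	miR-17-5p	PPARG
miranda	miR-17-5p	PPARG
miranda	miR-17-5p	RXRA
targetscan	miR-193	PPARG
miranda	miR-193	PPARG
miranda	miR-193	RXRA
targetscan	miR-25	PPARG
miranda	miR-25	PPARG
miranda	miR-25	RXRA
targetscan	miR-340-5p	PPARG
miranda	miR-340-5p	PPARG
miranda	miR-340-5p	RXRA
targetscan	miR-34a/miR-34c	PPARG
miranda	miR-34a/miR-34c	PPARG
miranda	miR-34a/miR-34c	RXRA
targetscan	miR-29a/miR-29b/miR-29c	PPARG
targetscan	miR-29a/miR-29b/miR-29c	RXRA
miranda	miR-29a/miR-29b/miR-29c	PPARG
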