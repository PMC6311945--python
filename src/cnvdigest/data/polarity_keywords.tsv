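# Polarity keywords: <direction>\t<word>, matched case-insensitively as
# whole tokens within the sentence containing a CNV mention.
loss	deletion
loss	deletions
loss	deleted
loss	loss
loss	losses
loss	microdeletion
loss	microdeletions
gain	duplication
gain	duplications
gain	duplicated
gain	amplification
gain	amplifications
gain	amplified
gain	gain
gain	gains
gain	gained
gain	triplication
gain	triplications
gain	microduplication
gain	microduplications
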