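variable,response,cases,controls
race,White,271,271
race,African-American,232,232
inflammation,none,213,197
inflammation,chronic_only,258,263
inflammation,chronic_and_or_acute,32,43
tumor_stage,1,374,
tumor_stage,2,118,
tumor_stage,3,7,
tumor_stage,4,4,
gleason_group,1,232,
gleason_group,2,116,
gleason_group,3,47,
gleason_group,4,55,
gleason_group,5,32,
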