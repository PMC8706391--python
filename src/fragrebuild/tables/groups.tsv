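# experiment groups: group number, comma-separated ligand ids
1	M61,M08,M17,M24,M60
2	M35,M36,M69,M70,M17,M24,M60,M05,M18,M19
3	M01,M02,M03,M37,M38,M39,M17,M24,M60,M05,M18,M19,M20,M21,M59
4	M31,M32,M33,M34,M65,M66,M67,M68,M17,M24,M60,M05,M18,M19,M20,M21,M22,M51,M58,M59
5	M04,M06,M07,M09,M10,M40,M41,M42,M43,M44,M17,M24,M60,M05,M18,M19,M20,M21,M22,M23,M51,M52,M53,M58,M59
6	M25,M26,M27,M28,M29,M30,M48,M49,M50,M62,M63,M64,M17,M24,M60,M05,M18,M19,M20,M21,M22,M23,M51,M52,M53,M71,M54,M55,M58,M59
7	M11,M12,M13,M14,M15,M25,M26,M27,M45,M46,M47,M48,M49,M50,M62,M63,M17,M24,M60,M05,M18,M19,M20,M21,M22,M23,M51,M52,M53,M71,M54,M55,M56,M58,M59
8	M61,M01,M02,M03,M04,M06,M07,M09,M10,M11,M27,M28,M29,M30,M31,M32,M33,M34,M35,M36,M08,M37,M38,M39,M40,M41,M42,M43,M44,M45,M50,M62,M63,M64,M65,M66,M67,M68,M69,M70
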