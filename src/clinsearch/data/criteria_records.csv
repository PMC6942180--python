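id,trial_id,type,support,sources,obstacles
CR001,CT1,inclusion,full,P,o
CR002,CT1,inclusion,full,P,o
CR003,CT2,inclusion,full,P,o
CR004,CT2,inclusion,full,P,o
CR005,CT3,inclusion,full,B,o
CR006,CT4,inclusion,full,B,o
CR007,CT1,exclusion,full,B,o
CR008,CT1,exclusion,full,B,o
CR009,CT2,exclusion,full,B,o
CR010,CT4,exclusion,full,B,o
CR011,CT4,exclusion,full,B,o
CR012,CT2,inclusion,accurate,P,d
CR013,CT3,inclusion,accurate,D,d
CR014,CT5,inclusion,accurate,D,d
CR015,CT1,exclusion,accurate,D,d
CR016,CT1,exclusion,accurate,D,d
CR017,CT1,exclusion,accurate,D,d
CR018,CT1,exclusion,accurate,D,d
CR019,CT1,exclusion,accurate,D,d
CR020,CT2,exclusion,accurate,D,d
CR021,CT2,exclusion,accurate,P+N,d
CR022,CT2,exclusion,accurate,B+D,d
CR023,CT2,exclusion,accurate,B+D,d
CR024,CT2,exclusion,accurate,B+D,d
CR025,CT3,exclusion,accurate,D+N,d
CR026,CT3,exclusion,accurate,D+N,d
CR027,CT4,exclusion,accurate,D+N,d
CR028,CT4,exclusion,accurate,D+N,d
CR029,CT4,exclusion,accurate,D+N,d
CR030,CT1,inclusion,broad,S,s
CR031,CT2,inclusion,broad,S,s
CR032,CT3,inclusion,broad,B,s
CR033,CT4,inclusion,broad,B,s
CR034,CT4,inclusion,broad,D,s
CR035,CT5,inclusion,broad,D,s
CR036,CT1,exclusion,broad,D,s
CR037,CT1,exclusion,broad,D,s
CR038,CT1,exclusion,broad,D,s
CR039,CT1,exclusion,broad,D,s
CR040,CT1,exclusion,broad,N,s
CR041,CT1,exclusion,broad,N,s
CR042,CT2,exclusion,broad,N,s
CR043,CT2,exclusion,broad,N,s
CR044,CT2,exclusion,broad,N,s
CR045,CT2,exclusion,broad,N,s
CR046,CT3,exclusion,broad,N,s
CR047,CT4,exclusion,broad,S+N,s
CR048,CT4,exclusion,broad,B+N,s
CR049,CT4,exclusion,broad,D+N,s
CR050,CT4,exclusion,broad,D+N,s
CR051,CT5,exclusion,broad,D+N,s
CR052,CT5,exclusion,broad,D+N,s
CR053,CT5,exclusion,broad,S+D+N,s
CR054,CT5,exclusion,broad,S+D+N,s
CR055,CT1,inclusion,inaccurate,N,"d,s"
CR056,CT4,inclusion,inaccurate,N,"d,s"
CR057,CT5,inclusion,inaccurate,N,"d,s"
CR058,CT5,inclusion,inaccurate,N,"d,s"
CR059,CT1,exclusion,inaccurate,N,"d,s"
CR060,CT2,exclusion,inaccurate,B+N,"d,s"
CR061,CT4,exclusion,inaccurate,D+N,"d,s"
CR062,CT5,exclusion,inaccurate,P+S+D,"d,s"
CR063,CT5,exclusion,inaccurate,S+D+N,"d,s"
CR064,CT5,exclusion,inaccurate,D+N+I,"d,s"
CR065,CT2,inclusion,none,N,"d,t"
CR066,CT5,inclusion,none,N,"d,t"
CR067,CT5,inclusion,none,I,"d,t"
CR068,CT2,exclusion,none,I,"d,t"
CR069,CT4,exclusion,none,I,"d,t"
CR070,CT5,exclusion,none,D+N,"d,t"
CR071,CT5,exclusion,none,D+N,"d,t"
CR072,CT5,exclusion,none,D+N,"d,t"
CR073,CT5,exclusion,none,N+I,"d,t"
CR074,CT5,exclusion,none,S+D+N,"d,t"
CR075,CT1,inclusion,not_applicable,I,e
CR076,CT1,inclusion,not_applicable,I,e
CR077,CT2,inclusion,not_applicable,I,e
CR078,CT2,inclusion,not_applicable,I,e
CR079,CT2,inclusion,not_applicable,I,e
CR080,CT2,inclusion,not_applicable,I,e
CR081,CT3,inclusion,not_applicable,I,e
CR082,CT3,inclusion,not_applicable,I,e
CR083,CT4,inclusion,not_applicable,I,e
CR084,CT4,inclusion,not_applicable,I,e
CR085,CT4,inclusion,not_applicable,I,e
CR086,CT5,inclusion,not_applicable,I,e
CR087,CT5,inclusion,not_applicable,I,e
CR088,CT5,inclusion,not_applicable,I,e
CR089,CT1,exclusion,not_applicable,I,e
CR090,CT1,exclusion,not_applicable,I,e
CR091,CT2,exclusion,not_applicable,I,e
CR092,CT3,exclusion,not_applicable,I,e
CR093,CT4,exclusion,not_applicable,I,e
CR094,CT4,exclusion,not_applicable,I,e
CR095,CT5,exclusion,not_applicable,I,e
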